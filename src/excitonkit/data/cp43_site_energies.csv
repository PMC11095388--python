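site,gas_energy_ev,gas_fosc,isolated_energy_ev,isolated_fosc,isolated_shift_mev,full_energy_ev,full_fosc,full_shift_mev,pmm_mean_ev,pmm_std_ev
C1,1.868,0.22,1.850,0.20,-18,1.846,0.19,-22,1.873,0.005
C2,1.879,0.22,1.870,0.20,-9,1.867,0.20,-12,1.894,0.010
C3,1.868,0.22,1.866,0.20,-2,1.861,0.20,-7,1.867,0.005
C4,1.913,0.23,1.927,0.19,14,1.928,0.17,15,1.945,0.014
C5,1.966,0.23,1.944,0.22,-22,1.938,0.25,-28,1.915,0.011
C6,1.895,0.22,1.954,0.21,59,1.970,0.21,75,1.963,0.026
C7,1.886,0.23,1.897,0.20,11,1.885,0.21,-1,1.890,0.008
C8,1.893,0.22,1.883,0.23,-10,1.915,0.23,22,1.895,0.005
C9,1.897,0.23,1.881,0.23,-16,1.881,0.22,-16,1.912,0.008
C10,1.901,0.22,1.939,0.23,38,1.955,0.23,54,1.942,0.013
C11,1.916,0.22,1.998,0.22,82,1.983,0.24,67,1.964,0.020
C12,1.922,0.22,1.938,0.21,16,1.926,0.21,4,1.925,0.010
C13,1.917,0.23,1.930,0.22,13,1.961,0.22,44,1.937,0.018
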
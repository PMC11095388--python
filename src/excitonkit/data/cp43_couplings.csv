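site,C1,C2,C3,C4,C5,C6,C7,C8,C9,C10,C11,C12,C13
C1,,10.89,21.90,3.09,-3.07,-12.22,21.05,7.15,10.89,2.70,-2.52,0.63,-0.11
C2,,,8.14,154.07,-8.67,-16.15,-1.01,16.94,23.26,73.09,5.05,12.33,-10.27
C3,,,,-36.43,4.48,-0.45,7.88,-4.39,-11.26,23.04,8.19,25.02,5.71
C4,,,,,-3.40,4.57,-2.08,-1.53,-0.97,-34.68,-4.46,-4.72,5.09
C5,,,,,,25.46,-98.32,-5.90,-31.38,-1.18,-0.81,-1.55,5.03
C6,,,,,,,-77.69,-1.14,-32.26,-12.14,-4.85,-4.15,10.23
C7,,,,,,,,17.84,-112.59,-4.61,-9.06,-34.46,26.34
C8,,,,,,,,,130.37,66.94,1.78,2.11,-5.16
C9,,,,,,,,,,16.20,-117.64,36.43,-6.15
C10,,,,,,,,,,,-97.23,19.40,-11.76
C11,,,,,,,,,,,,25.24,-13.91
C12,,,,,,,,,,,,,-48.50
C13,,,,,,,,,,,,,
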
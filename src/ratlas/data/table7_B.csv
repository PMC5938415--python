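pair,case_label,tag,x_mm,y_mm
PW26_S26,00/115 (5b),a,-0.12456,-0.34712
PW26_S26,00/123 (5b),b,-0.12040,0.07792
PW31_S29,99/153 (4),a,0.29084,-0.41396
PW31_S29,99/144 (4),b,-0.11252,-0.51160
PW31_S29,99/152 (4),c,-0.13288,-0.49116
PW31_S29,99/138 (4),d,-0.14044,-0.58232
PW31_S29,00/049 (5a),e,-0.12124,-0.50012
PW31_S29,00/036 (5a),f,-0.22216,-0.52308
PW31_S29,99/151 (4),g,-0.28208,-0.62544
PW31_S29,00/044 (5a),h,-0.19492,-0.64652
PW31_S29,00/092 (*),i,-0.12868,-0.63420
PW31_S29,00/039 (5a),j,0.10288,-0.62924
PW31_S29,99/143 (4),k,0.55008,-0.50312
PW31_S29,99/137 (4),l,0.47464,-0.58256
PW31_S29,00/057 (*),m,-0.01672,-0.84860
PW31_S29,99/147 (4),n,0.12672,-0.80544
PW31_S29,00/084 (*),o,0.14808,-0.80820
PW31_S29,00/050 (5a),p,0.16744,-0.89124
PW31_S29,99/135 (4),q,0.33240,-0.80776
PW31_S29,00/086 (*),r,0.43420,-0.85048
PW33_S30,99/153 (4),a,-0.01832,-0.44964
PW33_S30,99/144 (4),b,0.20692,-0.60216
PW33_S30,99/152 (4),c,0.18056,-0.79532
PW33_S30,99/138 (4),d,0.12720,-0.81544
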
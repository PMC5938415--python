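pair,case_label,tag,x_mm,y_mm
PW26_S26,00/115 (5b),a,-0.12776,-0.11052
PW26_S26,00/123 (5b),b,-0.12360,0.53560
PW31_S29,99/153 (4),a,0.20612,0.16380
PW31_S29,99/144 (4),b,-0.10444,0.16428
PW31_S29,99/152 (4),c,-0.12844,0.18468
PW31_S29,99/138 (4),d,-0.13240,0.09352
PW31_S29,00/049 (5a),e,-0.11320,0.17572
PW31_S29,00/036 (5a),f,-0.21412,0.15276
PW31_S29,99/151 (4),g,-0.32236,-0.04632
PW31_S29,00/044 (5a),h,-0.21908,-0.09960
PW31_S29,00/092 (*),i,-0.15284,-0.08728
PW31_S29,00/039 (5a),j,0.04104,-0.09264
PW31_S29,99/143 (4),k,0.31640,-0.18180
PW31_S29,99/137 (4),l,0.24096,-0.26124
PW31_S29,00/057 (*),m,-0.21908,-0.54960
PW31_S29,99/147 (4),n,-0.04248,-0.48416
PW31_S29,00/084 (*),o,-0.02108,-0.48688
PW31_S29,00/050 (5a),p,-0.00176,-0.56996
PW31_S29,99/135 (4),q,0.16320,-0.48648
PW31_S29,00/086 (*),r,0.26500,-0.52916
PW33_S30,99/153 (4),a,-0.01084,-0.14860
PW33_S30,99/144 (4),b,0.21572,-0.30200
PW33_S30,99/152 (4),c,0.18920,-0.49628
PW33_S30,99/138 (4),d,0.13552,-0.51648
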
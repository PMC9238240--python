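site_id,occupancy,e_sw,e_ww,e_tot,ts_trans,ts_orient,ts_tot,kss_score
W13,0.56,-2.73,-5.87,-8.60,1.09,-0.98,0.11,0.52
W3,0.99,-4.63,-4.38,-9.01,2.20,-1.86,0.33,0.51
W28,0.34,-1.72,-7.00,-8.72,0.66,-0.43,0.23,0.27
W14,0.52,-2.41,-6.87,-9.28,1.02,-0.77,0.25,0.13
W26,0.35,-1.28,-7.92,-9.20,0.62,-0.54,0.08,0.11
W16,0.49,-3.98,-5.33,-9.31,1.23,-0.93,0.31,0.11
W23,0.45,-3.33,-6.33,-9.66,0.92,-0.91,0.00,-0.06
W29,0.32,-0.74,-9.08,-9.83,0.60,-0.40,0.19,-0.10
W31,0.29,-8.19,-1.68,-9.87,1.01,-1.03,-0.01,-0.10
W30,0.28,-1.57,-8.34,-9.91,0.54,-0.63,-0.08,-0.11
W12,0.59,-7.43,-2.33,-9.76,1.95,-2.25,-0.30,-0.13
W25,0.34,-4.94,-5.13,-10.07,0.81,-1.00,-0.19,-0.18
W10,0.69,-6.03,-3.79,-9.82,1.54,-1.29,0.25,-0.20
W17,0.48,-3.17,-6.84,-10.01,0.90,-1.16,-0.26,-0.23
W21,0.43,-12.59,2.45,-10.14,1.46,-1.50,-0.04,-0.26
W18,0.48,-3.63,-6.47,-10.10,1.08,-0.50,0.59,-0.27
W24,0.40,-2.96,-7.46,-10.42,0.98,-0.46,0.53,-0.36
W19,0.45,-7.74,-2.79,-10.54,1.09,-1.27,-0.17,-0.45
W27,0.37,-9.48,-1.46,-10.94,0.96,-1.49,-0.52,-0.52
W7,0.81,-8.44,-1.92,-10.36,1.69,-1.55,0.14,-0.67
W15,0.50,-8.53,-2.45,-10.98,1.27,-1.27,0.01,-0.72
W20,0.45,-9.11,-2.07,-11.18,1.23,-1.64,-0.41,-0.74
W11,0.67,-8.69,-2.23,-10.91,1.56,-2.04,-0.48,-0.93
W8,0.80,-4.73,-6.01,-10.74,1.60,-2.27,-0.68,-0.97
W9,0.77,-6.54,-4.30,-10.84,2.13,-2.56,-0.43,-1.01
W22,0.43,-13.37,0.82,-12.55,1.29,-2.04,-0.75,-1.30
W5,0.95,-6.73,-5.82,-12.55,1.94,-2.72,-0.79,-2.87
W2,1.00,-15.69,1.85,-13.83,2.44,-2.99,-0.55,-4.30
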
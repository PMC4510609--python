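wavelength_nm,k
400,0.35
410,0.47
420,0.60
430,0.73
440,0.85
450,0.95
460,1.00
470,0.95
480,0.85
490,0.62
500,0.38
510,0.22
520,0.12
530,0.05
540,0.02
550,0.01
560,0.00
600,0.00
700,0.00
800,0.00
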
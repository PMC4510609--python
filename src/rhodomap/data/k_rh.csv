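wavelength_nm,k
400,0.30
410,0.31
420,0.34
430,0.41
440,0.52
450,0.64
460,0.76
470,0.87
480,0.94
490,0.99
500,1.00
510,0.96
520,0.87
530,0.72
540,0.55
550,0.38
560,0.23
570,0.12
580,0.05
590,0.00
600,0.00
700,0.00
800,0.00
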
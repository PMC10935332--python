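molecule,atom,shift_ppm
ribitol,H1R,3.79
ribitol,H1S,3.64
ribitol,H2,3.81
ribitol,H3,3.68
ribitol,C1,65.1
ribitol,C2,74.8
ribitol,C3,74.9
d-arabitol,H1R,3.66
d-arabitol,H1S,3.66
d-arabitol,H2,3.92
d-arabitol,H3,3.58
d-arabitol,H4,3.74
d-arabitol,H5R,3.81
d-arabitol,H5S,3.66
d-arabitol,C1,65.8
d-arabitol,C2,73.0
d-arabitol,C3,73.2
d-arabitol,C4,73.7
d-arabitol,C5,65.7
xylitol,H1R,3.70
xylitol,H1S,3.63
xylitol,H2,3.79
xylitol,H3,3.63
xylitol,C1,65.3
xylitol,C2,74.6
xylitol,C3,73.5
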
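molecule,coupling_name,hertz,available
ribitol,"3J(H1R,H2)",3.00,yes
ribitol,"3J(H1S,H2)",7.20,yes
ribitol,"3J(H2,H3)",6.50,yes
ribitol,"2J(H1R,H1S)",-12.70,yes
ribitol,"3J(C1,H3)",3.8,yes
ribitol,"3J(C3,H1S)",2.9,yes
ribitol,"3J(C3,H1R)",,no
ribitol,"3J(C3,H5)",,no
ribitol,"3J(C5,H2)",,no
d-arabitol,"3J(H1R,H2)",5.00,yes
d-arabitol,"3J(H1S,H2)",7.55,yes
d-arabitol,"3J(H2,H3)",2.00,yes
d-arabitol,"3J(H3,H4)",8.4,yes
d-arabitol,"3J(H4,H5R)",3.05,yes
d-arabitol,"3J(H4,H5S)",6.50,yes
d-arabitol,"2J(H1R,H1S)",-11.55,yes
d-arabitol,"2J(H5R,H5S)",-11.00,yes
d-arabitol,"3J(C1,H3)",,no
d-arabitol,"3J(C3,H1S)",,no
d-arabitol,"3J(C3,H1R)",,no
d-arabitol,"3J(C3,H5)",,no
d-arabitol,"3J(C5,H2)",,no
xylitol,"3J(H1R,H2)",4.5,yes
xylitol,"3J(H1S,H2)",7.5,yes
xylitol,"3J(H2,H3)",4.6,yes
xylitol,"2J(H1R,H1S)",-11.7,yes
xylitol,"3J(C1,H3)",5.4,yes
xylitol,"3J(C3,H1R)",4.5,yes
xylitol,"3J(C5,H2)",10.0,yes
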
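# N-end rule protein half-lives, mammalian reticulocytes in vitro (hours),
# as tabulated by the Expasy ProtParam tool (Bachmair/Varshavsky N-end rule).
# Proline is reported as ">20 h" and recorded here as 20.
residue,half_life_hours
A,4.4
R,1.0
N,1.4
D,1.1
C,1.2
Q,0.8
E,1.0
G,30.0
H,3.5
I,20.0
L,5.5
K,1.3
M,30.0
F,1.1
P,20.0
S,1.9
T,7.2
W,2.8
Y,2.8
V,100.0
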
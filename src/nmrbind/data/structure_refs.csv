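residue_type,atom,helix_ppm,strand_ppm
A,CA,3.0,-1.4
A,CB,-0.4,2.2
A,CO,1.7,-1.6
R,CA,2.6,-1.4
R,CB,-0.4,2.2
R,CO,1.7,-1.6
N,CA,2.6,-1.4
N,CB,-0.4,2.2
N,CO,1.7,-1.6
D,CA,2.6,-1.4
D,CB,-0.4,2.2
D,CO,1.7,-1.6
C,CA,2.6,-1.4
C,CB,-0.4,2.2
C,CO,1.7,-1.6
Q,CA,2.6,-1.4
Q,CB,-0.4,2.2
Q,CO,1.7,-1.6
E,CA,2.6,-1.4
E,CB,-0.4,2.2
E,CO,1.7,-1.6
G,CA,2.6,-1.4
G,CO,1.7,-1.6
H,CA,2.6,-1.4
H,CB,-0.4,2.2
H,CO,1.7,-1.6
I,CA,2.6,-1.8
I,CB,-0.4,2.2
I,CO,1.7,-1.6
L,CA,3.0,-1.4
L,CB,-0.4,2.2
L,CO,1.7,-1.6
K,CA,2.6,-1.4
K,CB,-0.4,2.2
K,CO,1.7,-1.6
M,CA,2.6,-1.4
M,CB,-0.4,2.2
M,CO,1.7,-1.6
F,CA,2.6,-1.4
F,CB,-0.4,2.2
F,CO,1.7,-1.6
P,CA,2.6,-1.4
P,CB,-0.4,2.2
P,CO,1.7,-1.6
S,CA,2.6,-1.4
S,CB,-0.4,2.2
S,CO,1.7,-1.6
T,CA,2.6,-1.8
T,CB,-0.4,2.2
T,CO,1.7,-1.6
W,CA,2.6,-1.4
W,CB,-0.4,2.2
W,CO,1.7,-1.6
Y,CA,2.6,-1.4
Y,CB,-0.4,2.2
Y,CO,1.7,-1.6
V,CA,2.6,-1.8
V,CB,-0.4,2.2
V,CO,1.7,-1.6
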
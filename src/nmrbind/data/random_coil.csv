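residue_type,atom,shift_ppm
A,CA,52.5
A,CB,19.1
A,CO,177.8
R,CA,56.0
R,CB,30.9
R,CO,176.3
N,CA,52.8
N,CB,37.9
N,CO,175.8
D,CA,54.2
D,CB,41.1
D,CO,176.3
C,CA,58.2
C,CB,28.0
C,CO,174.6
Q,CA,55.7
Q,CB,29.4
Q,CO,176.0
E,CA,56.6
E,CB,29.9
E,CO,176.6
G,CA,45.1
G,CO,174.9
H,CA,55.0
H,CB,29.0
H,CO,174.1
I,CA,61.1
I,CB,38.8
I,CO,176.4
L,CA,55.1
L,CB,42.4
L,CO,177.6
K,CA,56.2
K,CB,33.1
K,CO,176.6
M,CA,55.4
M,CB,32.9
M,CO,176.3
F,CA,57.7
F,CB,39.6
F,CO,175.8
P,CA,63.3
P,CB,32.1
P,CO,177.3
S,CA,58.3
S,CB,63.8
S,CO,174.6
T,CA,61.8
T,CB,69.8
T,CO,174.7
W,CA,57.5
W,CB,29.6
W,CO,176.1
Y,CA,57.9
Y,CB,38.8
Y,CO,175.9
V,CA,62.2
V,CB,32.9
V,CO,176.3
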
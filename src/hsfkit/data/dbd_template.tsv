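residue	element
F	a1
V	a1
P	a1
K	a1
L	a1
N	a1
T	a1
M	a1
L	a1
D	a1
E	a1
G	-
S	-
K	b1
V	b1
S	b1
W	b1
S	b1
P	-
N	-
G	-
R	b2
S	b2
F	b2
E	b2
I	b2
W	-
D	-
P	a2
H	a2
E	a2
F	a2
A	a2
R	a2
D	a2
L	a2
L	a2
P	a2
K	a2
Y	-
F	-
K	-
H	-
N	-
N	a3
F	a3
S	a3
S	a3
F	a3
V	a3
R	a3
Q	a3
L	a3
N	a3
T	a3
Y	-
G	-
F	-
R	-
K	-
V	b3
D	b3
P	b3
D	b3
R	b3
W	-
E	-
F	b4
A	b4
N	b4
R	b4
E	b4
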
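aa	a	b	c	d	e	f	g
L	3.5	0.8	0.8	3.0	0.8	0.8	0.8
I	3.0	0.8	0.8	2.6	0.8	0.8	0.8
M	2.4	0.9	0.9	2.2	0.9	0.9	0.9
V	2.2	0.8	0.8	2.0	0.8	0.8	0.8
F	1.6	0.7	0.7	1.5	0.7	0.7	0.7
A	1.8	1.2	1.2	1.5	1.2	1.2	1.2
E	0.6	1.5	1.5	0.6	1.6	1.4	1.4
K	0.7	1.4	1.4	0.6	1.4	1.3	1.5
Q	0.8	1.4	1.3	0.7	1.4	1.3	1.3
R	0.8	1.3	1.3	0.7	1.3	1.2	1.4
N	0.6	1.1	1.1	0.6	1.1	1.1	1.0
D	0.4	1.1	1.2	0.4	1.1	1.2	1.0
S	0.7	1.0	1.0	0.7	1.0	1.0	1.0
T	0.7	1.0	1.0	0.7	1.0	0.9	0.9
H	0.7	0.9	0.9	0.7	0.9	0.9	0.9
C	0.9	0.7	0.7	0.9	0.7	0.7	0.7
W	0.9	0.6	0.6	0.9	0.6	0.6	0.6
Y	1.0	0.8	0.8	1.0	0.8	0.8	0.8
G	0.3	0.9	0.9	0.3	0.9	0.9	0.9
P	0.1	0.1	0.1	0.1	0.1	0.1	0.1
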
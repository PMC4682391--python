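amino_acid	high_pct	low_pct
A	7.0	6.8
R	4.2	4.8
N	4.8	4.5
D	5.2	5.9
C	2.6	1.7
Q	3.9	4.2
E	5.7	7.0
G	7.8	6.6
H	2.1	2.3
I	4.7	5.3
L	8.2	9.0
K	5.7	6.4
M	1.7	2.3
F	3.5	4.0
P	4.9	4.7
S	8.6	6.7
T	6.7	6.0
W	1.7	1.4
Y	3.9	3.5
V	7.0	6.9
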
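# Background amino-acid frequencies derived from the BLOSUM62 alignment
# database, as used by the Jensen-Shannon divergence conservation score of
# Capra & Singh (2007, Bioinformatics 23:1875-1882).
# Format: '<residue> <frequency>' per line. The published values sum to
# 1.002; they are renormalized to exactly 1 when loaded.
A 0.078
R 0.051
N 0.041
D 0.052
C 0.024
Q 0.034
E 0.059
G 0.083
H 0.025
I 0.062
L 0.092
K 0.056
M 0.024
F 0.044
P 0.043
S 0.059
T 0.055
W 0.014
Y 0.034
V 0.072
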
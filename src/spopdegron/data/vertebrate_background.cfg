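# Vertebrate-like amino-acid background composition (approximate human
# proteome frequencies); alternative to the uniform 1/20 default.
A = 0.0702
C = 0.0230
D = 0.0473
E = 0.0710
F = 0.0365
G = 0.0657
H = 0.0263
I = 0.0433
K = 0.0573
L = 0.0996
M = 0.0213
N = 0.0359
P = 0.0631
Q = 0.0477
R = 0.0564
S = 0.0833
T = 0.0536
V = 0.0597
W = 0.0122
Y = 0.0266
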
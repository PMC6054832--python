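# Gonnet et al. 1992 amino acid substitution matrix (PAM250-scale log-odds)
      A     C     D     E     F     G     H     I     K     L     M     N     P     Q     R     S     T     V     W     Y
A   2.4   0.5  -0.3   0.0  -2.3   0.5  -0.8  -0.8  -0.4  -1.2  -0.7  -0.3   0.3  -0.2  -0.6   1.1   0.6   0.1  -3.6  -2.2
C   0.5  11.5  -3.2  -3.0  -0.8  -2.0  -1.3  -1.1  -2.8  -1.5  -0.9  -1.8  -3.1  -2.4  -2.2   0.1  -0.5   0.0  -1.0  -0.5
D  -0.3  -3.2   4.7   2.7  -4.5   0.1   0.4  -3.8   0.5  -4.0  -3.0   2.2  -0.7   0.9  -0.3   0.5   0.0  -2.9  -5.2  -2.8
E   0.0  -3.0   2.7   3.6  -3.9  -0.8   0.4  -2.7   1.2  -2.8  -2.0   0.9  -0.5   1.7   0.4   0.2  -0.1  -1.9  -4.3  -2.7
F  -2.3  -0.8  -4.5  -3.9   7.0  -5.2  -0.1   1.0  -3.3   2.0   1.6  -3.1  -3.8  -2.6  -3.2  -2.8  -2.2   0.1   3.6   5.1
G   0.5  -2.0   0.1  -0.8  -5.2   6.6  -1.4  -4.5  -1.1  -4.4  -3.5   0.4  -1.6  -1.0  -1.0   0.4  -1.1  -3.3  -4.0  -4.0
H  -0.8  -1.3   0.4   0.4  -0.1  -1.4   6.0  -2.2   0.6  -1.9  -1.3   1.2  -1.1   1.2   0.6  -0.2  -0.3  -2.0  -0.8   2.2
I  -0.8  -1.1  -3.8  -2.7   1.0  -4.5  -2.2   4.0  -2.1   2.8   2.5  -2.8  -2.6  -1.9  -2.4  -1.8  -0.6   3.1  -1.8  -0.7
K  -0.4  -2.8   0.5   1.2  -3.3  -1.1   0.6  -2.1   3.2  -2.1  -1.4   0.8  -0.6   1.5   2.7   0.1   0.1  -1.7  -3.5  -2.1
L  -1.2  -1.5  -4.0  -2.8   2.0  -4.4  -1.9   2.8  -2.1   4.0   2.8  -3.0  -2.3  -1.6  -2.2  -2.1  -1.3   1.8  -0.7   0.0
M  -0.7  -0.9  -3.0  -2.0   1.6  -3.5  -1.3   2.5  -1.4   2.8   4.3  -2.2  -2.4  -1.0  -1.7  -1.4  -0.6   1.6  -1.0  -0.2
N  -0.3  -1.8   2.2   0.9  -3.1   0.4   1.2  -2.8   0.8  -3.0  -2.2   3.8  -0.9   0.7   0.3   0.9   0.5  -2.2  -3.6  -1.4
P   0.3  -3.1  -0.7  -0.5  -3.8  -1.6  -1.1  -2.6  -0.6  -2.3  -2.4  -0.9   7.6  -0.2  -0.9   0.4   0.1  -1.8  -5.0  -3.1
Q  -0.2  -2.4   0.9   1.7  -2.6  -1.0   1.2  -1.9   1.5  -1.6  -1.0   0.7  -0.2   2.7   1.5   0.2   0.0  -1.5  -2.7  -1.7
R  -0.6  -2.2  -0.3   0.4  -3.2  -1.0   0.6  -2.4   2.7  -2.2  -1.7   0.3  -0.9   1.5   4.7  -0.2  -0.2  -2.0  -1.6  -1.8
S   1.1   0.1   0.5   0.2  -2.8   0.4  -0.2  -1.8   0.1  -2.1  -1.4   0.9   0.4   0.2  -0.2   2.2   1.5  -1.0  -3.3  -1.9
T   0.6  -0.5   0.0  -0.1  -2.2  -1.1  -0.3  -0.6   0.1  -1.3  -0.6   0.5   0.1   0.0  -0.2   1.5   2.5   0.0  -3.5  -1.9
V   0.1   0.0  -2.9  -1.9   0.1  -3.3  -2.0   3.1  -1.7   1.8   1.6  -2.2  -1.8  -1.5  -2.0  -1.0   0.0   3.4  -2.6  -1.1
W  -3.6  -1.0  -5.2  -4.3   3.6  -4.0  -0.8  -1.8  -3.5  -0.7  -1.0  -3.6  -5.0  -2.7  -1.6  -3.3  -3.5  -2.6  14.2   4.1
Y  -2.2  -0.5  -2.8  -2.7   5.1  -4.0   2.2  -0.7  -2.1   0.0  -0.2  -1.4  -3.1  -1.7  -1.8  -1.9  -1.9  -1.1   4.1   7.8
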
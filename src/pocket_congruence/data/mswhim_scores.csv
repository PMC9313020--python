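# MS-WHIM scores of the 20 natural amino acids: three principal components
# of molecular electrostatic-potential surface properties.
# Transcribed from Zaliani A, Gancia E (1999) J Chem Inf Comput Sci 39:525-533
# (the scale distributed with the R package Peptides as "MSWHIM").
aa,x,y,z
A,-0.73,0.20,-0.62
R,-0.22,0.26,1.27
N,0.14,0.20,-0.66
D,0.11,-1.00,-0.96
C,-0.66,0.26,-0.27
E,0.24,-0.39,-0.04
Q,0.30,1.00,-0.30
G,-0.31,-0.28,-0.75
H,0.84,0.67,-0.78
I,-0.91,0.83,-0.25
L,-0.74,0.72,-0.16
K,-0.51,0.08,0.60
M,-0.70,1.00,-0.32
F,0.76,0.85,-0.34
P,-0.43,0.73,-0.60
S,-0.80,0.61,-1.00
T,-0.58,0.85,-0.89
W,1.00,0.98,-0.47
Y,0.97,0.66,-0.16
V,-0.88,0.35,-0.58
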
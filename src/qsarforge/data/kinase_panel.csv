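kinase,pct_inhibition,sem
ABL,7.57,2.5
ALK,41.16,1.5
A-RAF,9.14,1.0
Aurora-A,49.77,5.5
B-RAFwt,23.37,0.9
BTK,16.96,0.8
DMPK,0.84,0.1
EGFR,19.93,2.0
ErbB2,2.17,0.9
ErbB4,13.67,2.8
FLT3,73.14,2.0
FMS,12.19,0
JAK1,-0.26,0
JAK2,3.76,0.5
JNK1(alpha1),0.76,0.1
KDR,18.76,1.0
cKIT,9.63,0
LCK,12.45,2.5
MEK1,1.50,0.2
MEK2,26.60,2.5
mTOR,7.83,0.3
PDGFRbeta,12.54,1.5
PI3Kalpha,5.85,0
PI3K-C2alpha,49.99,2.3
ROS,2.02,0.3
Src(T341M),1.57,0.3
STK33,15.65,0.5
TRKA,46.72,1.5
VRK1,3.93,0.5
V600E-B-RAF,99.48,0.09
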
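compound,target,ic50,unit
1b,V600E-B-RAF,245,nM
1e,V600E-B-RAF,144,nM
1f,V600E-B-RAF,83.8,nM
1h,V600E-B-RAF,191,nM
1i,V600E-B-RAF,142,nM
1j,V600E-B-RAF,78.2,nM
1m,V600E-B-RAF,82.6,nM
1n,V600E-B-RAF,120,nM
1r,V600E-B-RAF,11.2,nM
1s,V600E-B-RAF,18.4,nM
1t,V600E-B-RAF,194,nM
1u,V600E-B-RAF,45.1,nM
1v,V600E-B-RAF,100,nM
1w,V600E-B-RAF,121,nM
1z,V600E-B-RAF,241,nM
1zb,V600E-B-RAF,0.978,nM
1zc,V600E-B-RAF,1.9,nM
1zd,V600E-B-RAF,3.4,nM
1ze,V600E-B-RAF,28.8,nM
1zf,V600E-B-RAF,22.2,nM
1zg,V600E-B-RAF,15.8,nM
1zh,V600E-B-RAF,7.4,nM
1r,RAF1,45.6,nM
1s,RAF1,49.7,nM
1zb,RAF1,8.2,nM
1zc,RAF1,10.5,nM
1zd,RAF1,16.7,nM
1ze,RAF1,468.0,nM
1zf,RAF1,151.0,nM
1zg,RAF1,158.0,nM
1zh,RAF1,62.2,nM
1zb,FLT3,838,nM
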
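cell_line,group,compound,ic50,unit
A375,melanoma,1zb,0.46,uM
MDA-MB-435,melanoma,1zb,0.59,uM
SK-MEL-28,melanoma,1zb,0.38,uM
UACC-62,melanoma,1zb,0.18,uM
CCD1106K,normal_skin,1zb,9.26,uM
A375,melanoma,sorafenib,5.45,uM
MDA-MB-435,melanoma,sorafenib,3.16,uM
SK-MEL-28,melanoma,sorafenib,2.67,uM
UACC-62,melanoma,sorafenib,1.95,uM
CCD1106K,normal_skin,sorafenib,11.57,uM
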
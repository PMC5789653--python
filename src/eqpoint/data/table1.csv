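system,source,subgroup,n,r,method,transform,significance
calcium_pth,Jorde et al.,female,486,-0.195,pearson,identity,P<0.01
calcium_pth,Jorde et al.,male,460,-0.120,unspecified,identity,P<0.01
calcium_pth,Minisola et al.,female premenopause,35,-0.353,unspecified,identity,P<0.001
calcium_pth,Minisola et al.,female postmenopause,35,-0.064,unspecified,identity,NS
calcium_pth,Minisola et al.,male,45,-0.661,unspecified,identity,P<0.001
glucose_insulin,Gibson et al.,female,148,0.37,unspecified,log,P<0.001
glucose_insulin,Gibson et al.,male,142,0.06,unspecified,log,NS
glucose_insulin,Peplies et al.,male,3640,0.39,pearson,identity,P<0.001
glucose_insulin,Peplies et al.,female,3434,0.42,pearson,identity,P<0.001
glucose_insulin,Chen et al.,combined (male 1447 / female 1800),3247,0.0249,pearson,log,P=0.0001
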
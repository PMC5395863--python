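group,study_type,n_reviews,n_searched,pct_searched_printed,n_included,pct_included_printed,n_studies_total,n_studies_of_type,pct_studies_printed
ARI,non_english,57,57,100,11,19.3,398,28,7.0
ID,non_english,38,38,100,4,10.5,238,6,0.8
DPLP,non_english,34,33,97.1,0,0.0,144,0,0.0
total,non_english,129,128,99.2,15,11.7,780,34,4.4
ARI,unpublished,57,55,96.5,5,7.3,398,11,2.8
ID,unpublished,38,38,100,2,5.3,238,3,1.3
DPLP,unpublished,34,31,91.2,1,3.2,144,1,0.7
total,unpublished,129,124,96.1,8,5.6,780,15,1.9
ARI,dissertation,57,5,8.8,1,20.0,398,2,0.5
ID,dissertation,38,1,2.6,1,100,238,2,0.8
DPLP,dissertation,34,22,64.7,7,31.8,144,11,7.6
total,dissertation,129,28,21.7,9,32.1,780,15,1.9
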
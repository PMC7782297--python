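sample_id,ethnicity,paternal_origin_country,note,DYS456,DYS389I,DYS390,DYS389II,DYS458,DYS19,DYS385,DYS393,DYS391,DYS439,DYS635,DYS392,YGATAH4,DYS437,DYS438,DYS448
I1,Caucasian,Ireland,,15,13,24,29,17,15,11;14,13,11,11,23,13,12,15,12,19
I2,Caucasian,Ireland,,15,13,23,29,15,14,14;17,12,11,12,22,11,12,14,9,21
I3,Caucasian,Ireland,,16,12,24,29,16,14,11;14,13,11,12,23,13,12,15,12,19
I4,Caucasian,Ireland,,16,13,24,29,17,14,11;14,13,10,13,23,13,11,15,12,19
I5,Caucasian,Ireland,,15,13,24,30,17,14,11;14,14,10,12,23,13,11,15,12,19
I6,Caucasian,Ireland,,18,15,24,33,17,15,12;16,13,11,11,21,12,11,15,10,20
I7,Caucasian,Ireland,,15,13,24,29,18,14,11;14,13,11,11,23,13,13,15,12,19
I8,Caucasian,Ireland,,16,13,23,30,17,15,11;15,13,11,12,23,13,11,15,12,19
I9,Caucasian,Ireland,consistent with Dal Riata founder haplotype except DYS389II,16,13,25,29,17,14,11;13,13,11,12,23,14,12,15,12,18
I11,Caucasian,Ireland,,15,13,24,29,17,14,10;14,13,11,11,23,13,12,15,12,19
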
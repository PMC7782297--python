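sample_id,surname_group,ethnicity,paternal_origin_country,paternal_origin_county,birthplace,note,DYS456,DYS389I,DYS390,DYS389II,DYS458,DYS19,DYS385,DYS393,DYS391,DYS439,DYS635,DYS392,YGATAH4,DYS437,DYS438,DYS448
OB1,OBrien,Caucasian,Ireland,Kerry,,,16,12,24,28,18,14,11;14,13,11,12,23,13,12,15,12,19
OB2,OBrien,Caucasian,Ireland,,,,15,12,22,28,15,14,13;14,12,10,12,21,11,10,16,10,20
OB3,OBrien,Caucasian,Ireland,Limerick,,,17,14,23,30,16,14,12;14,13,11,13,23,13,13,14,12,19
OB4,OBrien,Caucasian,Ireland,,,,16,14,23,31,16,14,11;15,13,11,13,23,13,12,15,12,19
OB5,OBrien,Caucasian,Ireland,Clare,West Haven CT,,16,13,25,29,17,14,11;13,13,10,12,23,14,12,15,12,18
OB6,OBrien,Caucasian,Ireland,Clare,West Haven CT,,16,13,25,29,17,14,11;13,13,10,12,23,14,12,15,12,18
OB7,OBrien,Caucasian,Ireland,,,,16,14,24,31,18,14,11;14,13,11,11,23,13,12,15,12,18
OB8,OBrien,Caucasian,Ireland,Roscommon,,,17,14,24,31,17,15,11;15,13,10,10,21,11,11,15,10,20
OB9,OBrien,Caucasian,Ireland,,,consistent with Dal Riata founder haplotype except DYS389II,17,13,25,29,16,14,11;14,13,11,13,23,13,12,15;16,12,18
OB11,OBrien,Caucasian,Ireland,Limerick,,consistent with Dal Riata founder haplotype except DYS389II,15,13,25,29,18,14,11;14,13,11,11,23,13,12,15,12,19
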
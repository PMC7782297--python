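sample_id,note,DYS456,DYS389I,DYS390,DYS389II,DYS458,DYS19,DYS385,DYS393,DYS391,DYS439,DYS635,DYS392,YGATAH4,DYS437,DYS438,DYS448
C1,,14,12,22,28,15,14,12;14,13,10,10,24,10,11,16,11,19
C2,,15,13,23,31,17,14,13;20,14,10,10,24,10,11,16,11,19
C3,,14,14,23,33,17,14,13;16,14,10,11,22,12,11,14,10,20
C4,,15,14,24,30,17,14,11;14,13,11,14,23,13,12,15,12,19
C5,,16,14,25,30,17,14,11;14,13,10,12,23,13,12,15,12,18
C6,consistent with Dal Riata founder haplotype except DYS389II,16,13,25,29,16,14,11;14,13,11,11,23,13,12,15,12,19
C7,consistent with Dal Riata founder haplotype except DYS389II,16,13,25,29,17,14,11,13,11,12,23,13,12,15,12,19
C8,,16,13,24,29,19,14,10;14,13,10,12,24,13,11,14,12,18
C9,,15,13,24,29,17,14,11;15,13,10,11,24,13,12,15,12,19
C11,,15,13,21,32,17,16,16,14,10,14,21,11,11,14,11,20
C12,,16,13,23,29,18,14,11;14,13,10,11,23,13,12,14,12,19
C13,,17,13,24,30,15,13,16;18,13,10,12,24,11,12,14,10,20
C14,,17,14,24,30,16,15,11;14,13,10,11,23,11,12,14,11,19
C15,,16,12,23,29,17,14,16,13,10,13,21,13,10,14,9,18
C16,,15,12,23,29,18,14,13;16,12,10,11,24,11,12,15,9,20
C17,father-son pair with C18,15,14,25,31,16,15,11;14,13,11,10,23,14,12,14,10,19
C18,father-son pair with C17,15,14,25,31,16,15,11;14,13,11,10,23,14,12,14,10,19
C20,,15,13,24,29,17,14,11;14,13,11,13,23,13,12,14,12,19
C23,,17,14,25,31,17,14,11;13,13,11,12,23,14,12,15,12,18
C24,,17,14,25,31,17,14,11;13,13,11,12,23,14,12,15,12,19
C25,,15,13,24,29,17,14,11;15,13,10,11,23,13,12,15,12,19
C28,,15,13,24,30,17,16,14;15,13,11,12,23,11,11,15,10,20
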
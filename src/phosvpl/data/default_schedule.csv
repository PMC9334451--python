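subject,session,has_reading_test,has_video
S1,1,False,False
S1,2,True,True
S1,3,False,True
S1,4,False,True
S1,5,True,True
S1,6,False,True
S1,7,False,True
S1,8,False,True
S1,9,False,True
S1,10,False,True
S1,11,True,True
S1,12,False,True
S1,13,False,True
S1,14,False,True
S1,15,False,True
S1,16,False,True
S1,17,True,True
S1,18,False,True
S1,19,False,True
S1,20,True,True
S1,21,False,True
S1,22,False,True
S1,23,True,False
S2,1,False,False
S2,2,True,True
S2,3,False,True
S2,4,False,True
S2,5,False,True
S2,6,False,True
S2,7,False,True
S2,8,True,True
S2,9,False,True
S2,10,False,True
S2,11,True,True
S2,12,False,True
S2,13,False,True
S2,14,True,True
S2,15,False,True
S2,16,False,True
S2,17,False,True
S2,18,False,True
S2,19,False,True
S2,20,True,True
S2,21,False,True
S2,22,False,True
S2,23,True,False
S3,1,False,False
S3,2,True,True
S3,3,False,True
S3,4,False,True
S3,5,True,True
S3,6,False,True
S3,7,False,True
S3,8,False,True
S3,9,False,True
S3,10,False,True
S3,11,True,True
S3,12,False,True
S3,13,False,True
S3,14,True,True
S3,15,False,True
S3,16,False,True
S3,17,False,True
S3,18,False,True
S3,19,False,True
S3,20,True,True
S3,21,False,True
S3,22,False,True
S3,23,True,False
S4,1,False,False
S4,2,True,True
S4,3,False,True
S4,4,False,True
S4,5,True,True
S4,6,False,True
S4,7,False,True
S4,8,False,True
S4,9,False,True
S4,10,False,True
S4,11,True,True
S4,12,False,True
S4,13,False,True
S4,14,False,True
S4,15,False,True
S4,16,False,True
S4,17,True,True
S4,18,False,True
S4,19,False,True
S4,20,True,True
S4,21,False,True
S4,22,False,True
S4,23,True,False
S5,1,False,False
S5,2,True,True
S5,3,False,True
S5,4,False,True
S5,5,False,True
S5,6,False,True
S5,7,False,True
S5,8,True,True
S5,9,False,True
S5,10,False,True
S5,11,True,True
S5,12,False,True
S5,13,False,True
S5,14,False,True
S5,15,False,True
S5,16,False,True
S5,17,True,True
S5,18,False,True
S5,19,False,True
S5,20,True,True
S5,21,False,True
S5,22,False,True
S5,23,True,False
S6,1,False,False
S6,2,True,True
S6,3,False,True
S6,4,False,True
S6,5,False,True
S6,6,False,True
S6,7,False,True
S6,8,True,True
S6,9,False,True
S6,10,False,True
S6,11,True,True
S6,12,False,True
S6,13,False,True
S6,14,True,True
S6,15,False,True
S6,16,False,True
S6,17,False,True
S6,18,False,True
S6,19,False,True
S6,20,True,True
S6,21,False,True
S6,22,False,True
S6,23,True,False
S7,1,False,False
S7,2,True,True
S7,3,False,True
S7,4,False,True
S7,5,True,True
S7,6,False,True
S7,7,False,True
S7,8,True,True
S7,9,False,True
S7,10,False,True
S7,11,False,True
S7,12,False,True
S7,13,False,True
S7,14,True,True
S7,15,False,True
S7,16,False,True
S7,17,True,True
S7,18,False,True
S7,19,False,True
S7,20,False,True
S7,21,False,True
S7,22,False,True
S7,23,True,False
S8,1,False,False
S8,2,True,True
S8,3,False,True
S8,4,False,True
S8,5,True,True
S8,6,False,True
S8,7,False,True
S8,8,True,True
S8,9,False,True
S8,10,False,True
S8,11,False,True
S8,12,False,True
S8,13,False,True
S8,14,True,True
S8,15,False,True
S8,16,False,True
S8,17,True,True
S8,18,False,True
S8,19,False,True
S8,20,False,True
S8,21,False,True
S8,22,False,True
S8,23,True,False
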
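source_code,system,icd10_code
250.00,ICD9,E11.9
250.02,ICD9,E11.65
250.60,ICD9,E11.40
401.1,ICD9,I10
401.9,ICD9,I10
272.4,ICD9,E78.5
272.0,ICD9,E78.00
477.9,ICD9,J30.9
477.0,ICD9,J30.1
724.2,ICD9,M54.5
724.5,ICD9,M54.9
786.2,ICD9,R05
780.79,ICD9,R53.83
789.00,ICD9,R10.9
719.46,ICD9,M25.56
729.5,ICD9,M79.6
300.00,ICD9,F41.9
311,ICD9,F32.9
327.23,ICD9,G47.33
530.81,ICD9,K21.9
V70.0,ICD9,Z00.00
V04.81,ICD9,Z23
44054006,SNOMED,E11.9
38341003,SNOMED,I10
55822004,SNOMED,E78.5
61582004,SNOMED,J30.9
279039007,SNOMED,M54.5
49727002,SNOMED,R05
84229001,SNOMED,R53.83
21522001,SNOMED,R10.9
57676002,SNOMED,M25.56
48694002,SNOMED,F41.9
35489007,SNOMED,F32.9
78275009,SNOMED,G47.33
235595009,SNOMED,K21.9
171207006,SNOMED,Z00.00
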
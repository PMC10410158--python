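branch,scenario,wss_pa,provenance
C1,control,0.36,reference
C2-B1,control,0.24,reference
C2-B2,control,0.24,reference
C3-B1,control,0.27,reference
C3-B2,control,0.27,reference
C3-B3,control,0.27,reference
C3-B4,control,0.26,reference
C4-B1,control,0.28,reference
C4-B2,control,0.28,reference
C4-B3,control,0.26,reference
C4-B4,control,0.26,reference
C4-B5,control,0.26,reference
C4-B6,control,0.26,reference
C4-B7,control,0.28,reference
C4-B8,control,0.28,reference
C1,case_1/8,0.36,reference
C2-B1,case_1/8,0.21,reference
C2-B2,case_1/8,0.28,reference
C3-B1,case_1/8,0.30,reference
C3-B2,case_1/8,0.15,reference
C3-B3,case_1/8,0.31,reference
C3-B4,case_1/8,0.30,reference
C4-B1,case_1/8,0.27,reference
C4-B2,case_1/8,0.36,reference
C4-B3,case_1/8,0.00,reference
C4-B4,case_1/8,0.29,reference
C4-B5,case_1/8,0.32,reference
C4-B6,case_1/8,0.30,reference
C4-B7,case_1/8,0.31,reference
C4-B8,case_1/8,0.33,reference
C1,case_3/8,0.36,reference
C2-B1,case_3/8,0.09,reference
C2-B2,case_3/8,0.40,reference
C3-B1,case_3/8,0.00,reference
C3-B2,case_3/8,0.19,reference
C3-B3,case_3/8,0.45,reference
C3-B4,case_3/8,0.43,reference
C4-B1,case_3/8,0.00,reference
C4-B2,case_3/8,0.00,reference
C4-B3,case_3/8,0.01,reference
C4-B4,case_3/8,0.37,reference
C4-B5,case_3/8,0.44,reference
C4-B6,case_3/8,0.44,reference
C4-B7,case_3/8,0.51,reference
C4-B8,case_3/8,0.40,reference
C1,case_5/8,0.36,reference
C2-B1,case_5/8,0.16,reference
C2-B2,case_5/8,0.33,reference
C3-B1,case_5/8,0.00,reference
C3-B2,case_5/8,0.34,reference
C3-B3,case_5/8,0.35,reference
C3-B4,case_5/8,0.37,reference
C4-B1,case_5/8,0.00,reference
C4-B2,case_5/8,0.00,reference
C4-B3,case_5/8,0.01,reference
C4-B4,case_5/8,0.67,reference
C4-B5,case_5/8,0.02,reference
C4-B6,case_5/8,0.69,reference
C4-B7,case_5/8,0.78,reference
C4-B8,case_5/8,0.00,reference
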
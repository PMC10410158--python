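scenario,outlet_id,flowrate,out_split
control,INLET,3.01,1.00
control,O1,0.375,0.125
control,O2,0.380,0.126
control,O3,0.387,0.129
control,O4,0.378,0.126
control,O5,0.365,0.121
control,O6,0.369,0.123
control,O7,0.374,0.124
control,O8,0.379,0.126
case_1/8,INLET,2.95,1.00
case_1/8,O1,0.36,0.12
case_1/8,O2,0.46,0.16
case_1/8,O3,0,0
case_1/8,O4,0.41,0.14
case_1/8,O5,0.45,0.15
case_1/8,O6,0.41,0.14
case_1/8,O7,0.41,0.14
case_1/8,O8,0.45,0.15
case_3/8,INLET,3.65,1.00
case_3/8,O1,0,0
case_3/8,O2,0,0
case_3/8,O3,0,0
case_3/8,O4,0.66,0.18
case_3/8,O5,0.75,0.21
case_3/8,O6,0.75,0.21
case_3/8,O7,0.83,0.23
case_3/8,O8,0.66,0.18
case_5/8,INLET,4.74,1.00
case_5/8,O1,0,0
case_5/8,O2,0,0
case_5/8,O3,0,0
case_5/8,O4,1.5,0.32
case_5/8,O5,0,0
case_5/8,O6,1.58,0.33
case_5/8,O7,1.66,0.35
case_5/8,O8,0,0
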
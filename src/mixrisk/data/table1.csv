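css,pesticide,mec_mg_kg,pec_mg_kg,five_pec_mg_kg
SP,Oxyfluorfen,0.135,1.920,9.600
SP,Chlorantraniliprole,0.034,0.438,2.190
SP,Difenoconazole,0.020,0.135,0.675
SP,lambda-Cyhalothrin,0.025,0.033,0.164
SP,Boscalid,0.021,0.396,1.980
IT,Oxyfluorfen,0.046,1.920,9.600
IT,Chlorantraniliprole,0.014,0.438,2.190
IT,Difenoconazole,0.009,0.135,0.675
IT,lambda-Cyhalothrin,0.006,0.033,0.164
IT,Boscalid,0.018,0.396,1.980
PT,Chlorantraniliprole,0.006,0.438,2.190
PT,Boscalid,0.175,0.396,1.980
PT,Glyphosate,0.793,5.760,28.80
PT,Difenoconazole,0.005,0.135,0.675
PT,AMPA,1.910,2.036,10.18
FR,Chlorantraniliprole,0.013,0.438,2.190
FR,Boscalid,0.028,0.396,1.980
FR,Difenoconazole,0.010,0.135,0.675
FR,Cyflufenamid,0.004,0.024,0.118
FR,Glyphosate,0.257,5.760,28.80
CH,Difenoconazole,0.009,0.135,0.675
CH,Methoxyfenozide,0.009,0.091,0.455
CH,Myclobutanil,0.008,0.672,3.360
CH,AMPA,0.344,2.036,10.18
CH,Pirimicarb,0.023,0.160,0.800
HR,Boscalid,0.134,0.396,1.980
HR,Phosmet,0.006,0.400,2.000
HR,Acetamiprid,0.010,0.290,1.450
HR,AMPA,0.516,2.036,10.18
HR,Deltamethrin,0.036,0.022,0.110
SL,Bixafen,0.010,0.167,0.835
SL,Metolachlor-S,0.041,1.920,9.600
SL,AMPA,0.070,2.036,10.18
SL,Tebuconazole,0.007,0.185,0.925
SL,Terbuthylazine,0.009,1.125,5.625
CZ,Boscalid,0.018,0.396,1.980
CZ,Thiophanate-methyl,0.160,5.533,27.66
CZ,lambda-Cyhalothrin,0.002,0.033,0.164
CZ,Dimoxystrobin,0.017,0.047,0.235
CZ,Azoxystrobin,0.014,0.394,1.970
NL,lambda-Cyhalothrin,0.005,0.033,0.164
NL,Boscalid,0.018,0.396,1.980
NL,Azoxystrobin,0.021,0.394,1.970
NL,Bixafen,0.022,0.167,0.835
NL,Prosulfocarb,0.063,5.333,26.66
DK,Boscalid,0.008,0.396,1.980
DK,AMPA,0.115,2.036,10.18
DK,Diflufenican,0.018,0.250,1.250
DK,Fluopyram,0.008,0.261,1.303
DK,Pendimethalin,0.049,2.133,10.665
AR,Glyphosate,0.545,5.760,28.80
AR,lambda-Cyhalothrin,0.006,0.033,0.164
AR,AMPA,1.325,2.036,10.18
AR,Azoxystrobin,0.011,0.394,1.970
AR,Methoxyfenozide,0.012,0.091,0.455
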
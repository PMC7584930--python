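trial,drug_class,tumor,year,n,hr,p,p_is_bound,sifi
CA184-024,anti-CTLA-4,Melanoma,2015,502,0.72,0.001,0,7
CA184-029,anti-CTLA-4,Melanoma,2016,951,0.72,0.002,0,20
CA184-095,anti-CTLA-4,PC,2017,602,1.11,0.47,0,-21
CA184-156,anti-CTLA-4,SCLC,2016,954,0.94,0.44,0,-7
CA184-104,anti-CTLA-4,Squamous NSCLC,2017,749,0.91,0.17,0,-3
CA184-169,anti-CTLA-4,Melanoma,2017,727,0.84,0.04,0,1
CheckMate 017,anti-PD-1,Squamous NSCLC,2015,272,0.59,0.0003,0,8
CheckMate 057,anti-PD-1,Nonsquamous NSCLC,2015,582,0.73,0.004,0,5
CheckMate 025,anti-PD-1,RCC,2019,821,0.74,0.003,0,10
CheckMate 026,anti-PD-1,NSCLC,2017,423,1.02,0.77,0,-16
ATTRACTION-2,anti-PD-1,GC or GEJC,2017,493,0.63,0.0001,1,10
CheckMate 037,anti-PD-1,Melanoma,2018,405,0.95,0.59,0,-9
CheckMate 066,anti-PD-1,Melanoma,2019,418,0.46,0.0001,1,30
CheckMate 067,anti-PD-1,Melanoma,2018,631,0.65,0.0001,1,23
CheckMate 141,anti-PD-1,HNSCC,2018,361,0.68,0.001,0,5
ATTRACTION-3,anti-PD-1,ESCC,2019,419,0.77,0.015,0,2
CheckMate 078,anti-PD-1,NSCLC,2019,504,0.68,0.003,0,5
KEYNOTE-024,anti-PD-1,NSCLC,2016,305,0.60,0.01,0,6
KEYNOTE-006,anti-PD-1,Melanoma,2017,557,0.68,0.001,0,15
KEYNOTE-006,anti-PD-1,Melanoma,2017,555,0.68,0.001,0,14
KEYNOTE-040,anti-PD-1,HNSCC,2018,495,0.80,0.02,0,3
KEYNOTE-061,anti-PD-1,GC or GEJC,2018,395,0.82,0.06,0,-1
KEYNOTE-189,anti-PD-1,Nonsquamous NSCLC,2018,616,0.49,0.0001,1,40
KEYNOTE-407,anti-PD-1,Squamous NSCLC,2018,559,0.64,0.002,0,10
KEYNOTE-045,anti-PD-1,UC,2019,542,0.70,0.0005,0,9
KEYNOTE-048,anti-PD-1,HNSCC,2019,601,0.83,0.02,0,2
KEYNOTE-048,anti-PD-1,HNSCC,2019,559,0.77,0.005,0,5
KEYNOTE-183,anti-PD-1,MM,2019,249,1.61,0.14,0,-47
KEYNOTE-185,anti-PD-1,MM,2019,301,2.06,0.06,0,-79
KEYNOTE-240,anti-PD-1,HCC,2020,413,0.78,0.04,0,1
KEYNOTE-426,anti-PD-1,RCC,2019,861,0.53,0.0003,0,40
KEYNOTE-252,anti-PD-1,Melanoma,2019,706,1.13,0.44,0,-43
KEYNOTE-042,anti-PD-1,NSCLC,2019,1274,0.81,0.002,0,12
IMvigor211,anti-PD-L1,UC,2018,931,0.85,0.02,0,3
OAK,anti-PD-L1,NSCLC,2018,850,0.85,0.0003,0,12
IMpower150,anti-PD-L1,Nonsquamous NSCLC,2018,696,0.78,0.02,0,4
IMpower133,anti-PD-L1,SCLC,2018,403,0.70,0.01,0,3
IMpower130,anti-PD-L1,Nonsquamous NSCLC,2019,723,0.79,0.03,0,2
IMmotion151,anti-PD-L1,RCC,2019,915,0.93,0.71,0,-23
IMpassion130,anti-PD-L1,BRCA,2020,846,0.86,0.13,0,-4
IMblaze370,anti-PD-L1,CRC,2019,180,1.19,0.35,0,-12
IMblaze370,anti-PD-L1,CRC,2019,273,1.00,0.80,0,-9
JAVELIN Gastric 300,anti-PD-L1,GC or GEJC,2018,371,1.10,0.47,0,-13
JAVELIN Lung 200,anti-PD-L1,NSCLC,2018,529,0.90,0.36,0,-6
PACIFIC,anti-PD-L1,NSCLC,2018,713,0.68,0.001,0,15
CASPIAN,anti-PD-L1,SCLC,2019,537,0.73,0.003,0,6
CheckMate 067,combination,Melanoma,2018,629,0.54,0.0001,1,38
CheckMate 214,combination,RCC,2019,1096,0.71,0.003,0,18
CheckMate 227,combination,NSCLC,2019,1166,0.73,0.0001,1,24
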
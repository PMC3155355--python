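id,name,logbb,set,ref
CID: 2756,Cimetidine,-1.42,test,b37
CID: 72108,Icotidine,-2.00,training,b37
CID: 51671,Lupitidine,-1.06,test,b8
CID: 2803,Clonidine,0.11,training,b37
CID: 4992,Mepyramine,0.49,training,b37
CID: 3696,Imipramine,0.83,training,b37
CID: 5039,Ranitidine,-1.23,test,b37
CID: 50287,Tiotidine,-0.82,training,b37
CID: 91769,Zolantidine,0.14,test,b37
CID: 6569,Butanone,-0.08,test,b8
CID: 241,Benzene,0.37,training,b8
CID: 7282,3-Methylpentane,1.01,training,b8
CID: 11507,3-Methylhexane,0.90,training,b8
CID: 3776,2-Propanol,-0.15,training,b8
CID: 6560,2-Methylpropanol,-0.17,training,b8
CID: 7892,2-Methylpentane,0.97,test,b8
CID: 580244,"2,2-Dimethylbutane",1.04,test,b8
CID: 6278,"1,1,1-Trichloroethane",0.40,training,b37
CID: 3283,Diethyl ether,0.00,test,b8
CID: 3226,Enflurane,0.24,training,b8
CID: 702,Ethanol,-0.16,test,b8
CID: 9844,Fluroxene,0.13,training,b8
CID: 3562,Halothane,0.35,training,b8
CID: 8900,Heptane,0.81,training,b8
CID: 8058,Hexane,0.80,test,b8
CID: 3763,Isoflurane,0.42,test,b8
CID: 7296,Methylcyclopentane,0.93,test,b8
CID: 947,Nitrogen,0.03,training,b8
CID: 8003,Pentane,0.76,test,b8
CID: 1031,n-Propanol,-0.16,test,b8
CID: 180,Propanone,-0.15,test,b8
CID: 31300,Teflurane,0.27,training,b8
CID: 1140,Toluene,0.37,training,b8
CID: 2244,Acetylsalicylic acid,-0.50,training,b8
CID: 4737,Pentobarbital,0.12,training,b8
CID: 5983,Physostigmine,0.08,test,b8
CID: 338,Salicylic acid,-1.10,training,b8
CID: 5566,Trifluoro Perazine,1.44,training,b8
CID: 3121,Valproic acid,-0.22,training,b8
CID: 2520,Verapamil,-0.70,training,b8
CID: 5726,Zidovudine,-0.72,training,b8
CID: 3658,Hydroxyzine,0.39,test,b8
CID: 5452,Thioridazine,0.24,training,b8
CID: 2118,Alprazolam,0.04,test,b8
CID: 192706,Phenserine,1.00,training,b8
CID: 4192,Midazolam,0.36,test,b8
CID: 5284371,Codeine,0.55,test,b8
CID: 2726,Chlorpromazine,1.06,test,b8
CID: 4926,Promazine,1.23,training,b8
CID: 4463,Nevirapine,0.00,training,b8
CID: 3035905,Thioperamide,-0.16,training,b8
CID: 3043,Didanosine,-1.30,test,b8
CID: 3672,Ibuprofen,-0.18,training,b8
CID: 2206,Antipyrine,-2.00,test,b38
CID: 2153,Theophyline,-0.29,training,b8
CID: 1983,p-Acetamido phenol,-0.31,training,b8
CID: 948,Nitrous Oxide,0.03,training,b8
CID: 6348,Carbon bisulphide,0.60,training,b8
CID: 3715,Indomethacin,-1.26,training,b8
CID: 5362440,Indinavir,-0.75,training,b8
CID: 4616,Oxazepam,0.61,training,b8
CID: 2554,Carbamazepine,-0.14,test,b39
CID: 2555,Carbamazepine epoxide,-0.35,training,b39
CID: 2160,Amitriptyline,0.88,training,b8
CID: 2995,Desipramine,1.00,training,b8
CID: 4184,Mianserin,0.99,test,b8
CID: 166560,ORG 4428,0.82,test,b8
CID: 4205,Mirtazapine,0.53,training,b8
CID: 21844,Tibolone,0.40,training,b8
CID: 3151,Domperidone,-0.78,test,b8
CID: 5073,Risperidone,-0.67,test,b8
CID: 475100,9-OH-Risperidone,-0.02,training,b8
CID: 55482,Temelastine,-1.88,test,b8
CSID: 14922095,BBCPD13,-0.66,training,b37
CSID: 2992532,BBCPD15,-0.18,training,b37
CSID: 10439135,BBCPD57,-1.15,test,b37
CSID: 10442225,BBCPD58,-1.54,training,b37
CSID: 10442293,BBCPD17,-1.12,training,b37
CID: 9971484,BBCPD20,-0.46,training,b37
CID: 10498206,BBCPD21,-0.24,test,b37
CSID: 3167851,SB222200,0.30,training,b8
CSID: 2276,Y-G14,-0.30,training,b8
CSID: 72747,Y-G15,-0.06,training,b37
CID: 2519,Caffeine,-2.00,training,b38
CID: 2708,Chlorambucil,-1.60,training,b38
CID: 750,Glycine,-3.50,test,b38
CID: 5288826,Morphine,-2.70,test,b38
CID: 994,Phenylalanine,-1.30,test,b38
CID: 1775,Phenytoin,-2.20,training,b38
CID: 4946,Propranolol,-1.20,training,b38
CID: 444349,Taurocholic Acid,-4.10,training,b38
CID: 6575,Trichloroethylene,0.34,training,b37
CID: 450682,Carmustine,-0.52,training,b39
CSID: 8036856,ORG34167,0.00,training,b8
CSDI: 8620184,BBCPD22,-0.02,training,b37
BBCPD23,BBCPD23,0.69,test,b37
BBCPD24,BBCPD24,0.44,training,b37
BBCPD26,BBCPD26,0.22,test,b37
CSID: 6168,"1,1,1-Trifluoro-2-chloro ethane",0.08,training,b37
T7,T7,0.85,training,b37
CSDI: 23218171,BBCPD60,-0.73,training,b37
BBCPD18,BBCPD18,-0.27,training,b37
BBCPD19,BBCPD19,-0.28,test,b37
BBCPD16,BBCPD16,-1.57,training,b37
BBCPD14,BBCPD14,-0.12,test,b37
Y-G16,Y-G16,-0.42,training,b8
Y-G19,Y-G19,-1.30,test,b8
CSID: 5854406,Y-G20,-1.40,training,b37
CSID: 117961.,SKF89124,-0.43,training,b8
CSID: 4916,SKF101468,0.25,training,b37
CBZ-EPO,CBZ-EPO,-0.34,training,b37
CSID: 114837,L-663581,-0.30,training,b8
CSID: 8560187,"M1L-663,581",-1.34,training,b37
CSID: 8267285,M2L-663581,-1.82,training,b8
ORG5223,ORG5222,1.03,test,b8
CSID: 7972174,ORG12962,1.64,training,b8
ORG13011,ORG13011,0.16,training,b8
ORG32104,ORG32104,0.52,training,b8
ORG30526,ORG30526,0.39,training,b8
ICI17149,ICI17148,-0.04,test,b37
SK&F93320,SK&F93319,-1.30,training,b37
CBZ,CBZ,0.00,training,b37
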
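kind,name,cas,formula,mw,rt,quant_mz,qual_ions,is_name,working_lloq,working_uloq,final_conc
analyte,Acetoin,513-86-0,C4H8O2,88.11,3.382,88.0530,73.0295:15.0,Benzene-d6,0.02,10.00,
analyte,Butanoic Acid,107-92-6,C4H8O2,88.11,3.928,60.0211,73.0293:30.0,Pyridine-d5,0.08,10.00,
analyte,Benzaldehyde,100-52-7,C7H6O,106.12,5.141,106.0409,77.0395:84.0|105.0335:11.9,Chlorobenzene-d5,0.02,10.00,
analyte,"2,3,5-Trimethylpyrazine",14667-55-1,C7H10N2,122.17,5.203,122.0834,81.0583:11.1,Chlorobenzene-d5,0.02,10.00,
analyte,dl-Limonene,5989-27-5,C10H16,136.23,5.287,93.0705,121.1022:28.5|136.1257:33.5,Chlorobenzene-d5,0.02,10.00,
analyte,Eucalyptol,470-82-6,C10H18O,154.25,5.381,139.1129,154.1363:90.2,Chlorobenzene-d5,0.04,10.00,
analyte,Benzyl Alcohol,100-51-6,C7H8O,108.14,5.657,108.0566,79.0546:33.1|107.0498:62.0,Chlorobenzene-d5,0.02,5.00,
analyte,Furaneol,3658-77-3,C6H8O3,128.13,5.738,128.0478,85.0294:38.9,Chlorobenzene-d5,0.04,5.00,
analyte,Maltol,118-71-8,C6H6O3,126.11,6.132,126.0310,71.0136:15.2,Chlorobenzene-d5,0.16,10.00,
analyte,L-Menthol,2216-51-5,C10H20O,156.26,6.334,123.1180,109.1024:37.7|138.1415:64.8,Chlorobenzene-d5,0.02,10.00,
analyte,Methyl Salicylate,119-36-8,C8H8O3,152.15,6.489,120.0206,152.0469:79.1,Naphthalene-d8,0.02,10.00,
analyte,Ethyl Maltol,4940-11-8,C7H8O3,140.14,6.597,140.0471,139.0399:32.1,Naphthalene-d8,0.31,10.00,
analyte,(+)Pulegone,89-82-7,C10H16O,152.23,6.752,81.0706,152.1203:87.2,Naphthalene-d8,0.02,10.00,
analyte,Ethyl Salicylate,118-61-6,C9H10O3,166.17,6.887,120.0204,166.0624:64.4,Naphthalene-d8,0.02,10.00,
analyte,trans-Cinnamaldehyde,104-55-2,C9H8O,132.16,7.072,131.0499,132.0576:56.5,Naphthalene-d8,0.16,5.00,
analyte,Triacetin,102-76-1,C9H14O6,218.20,7.230,103.0398,145.0506:62.8,Naphthalene-d8,0.63,10.00,
analyte,Eugenol,97-53-0,C10H12O2,164.20,7.459,164.0830,149.0607:19.4,Naphthalene-d8,0.02,10.00,
analyte,Vanillin,121-33-5,C8H8O3,152.15,8.130,152.0474,151.0399:55.4,Naphthalene-d8,0.63,10.00,
analyte,Ethyl Vanillin,121-32-4,C9H10O3,166.17,8.571,137.0244,138.0321:66.6,Naphthalene-d8,0.31,10.00,
analyte,Isovanillin,621-59-0,C8H8O3,152.50,8.747,152.0475,151.0400:59.4,Acenaphthene-d10,0.16,10.00,
internal_standard,Benzene-d6,1076-43-3,C6H6,84.15,2.722,84.0851,85.0886:6.2,,,,1.0
internal_standard,Pyridine-d5,7291-22-7,C5H5N,84.13,3.477,84.0739,56.0568:13.0,,,,1.0
internal_standard,Chlorobenzene-d5,3114-55-4,C6H5Cl,117.59,4.184,117.0396,119.0369:29.5,,,,1.0
internal_standard,Naphthalene-d8,1146-65-2,C10H8,136.22,6.478,136.1131,137.1168:10.1,,,,1.0
internal_standard,Acenaphthene-d10,15067-26-2,C12H10,164.27,8.585,164.1416,165.1449:11.8,,,,1.0
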
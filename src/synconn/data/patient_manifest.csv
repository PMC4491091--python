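subject,group,age,laterality,tumor_location,tumor_type,tumor_grade
P01,LPMC,31,88,L. F1/F2/SMA/LPMC,AO,III
P02,LPMC,47,81,L. F1/F2/SMA/LPMC/F3op,AOA,III
P03,LPMC,36,88,L. F1/F2/SMA/LPMC/F3op,AA,III
P04,LPMC,49,100,L. F1/F2/LPMC,AO,III
P05,LPMC,34,100,L. F1/F2/LPMC/F3op,OD,II
P06,LPMC,29,81,L. F1/F2/LPMC/F3op,AO,III
P07,LPMC,27,45,L. F2/LPMC/F3op,DA,II
P08,F3,32,54,L. F1/F2/F3op/F3O/insula,AOA,III
P09,F3,20,100,L. F1/F2/F3op/F3O/insula,AO,III
P10,F3,31,100,L. F1/F2/F3op/F3t/insula/striatum,AOA,III
P11,F3,32,100,L. F1/F2/F3op/F3O/insula/striatum,DA,II
P12,F3,42,90,L. F2/F3op/F3O/insula/striatum,OA,II
P13,F3,29,87,L. F2/F3op/F3O/insula/striatum,OD,II
P14,F3,47,73,L. F3op/F3t/insula/striatum,DA,II
P15,Other,62,89,L. F1/F2/SMA,AO,III
P16,Other,24,68,L. F1/F2/SMA/striatum,OA,II
P17,Other,38,100,L. F1/F2/SMA/striatum,AOA,III
P18,Other,21,100,L. F1/F2/F3t/striatum,DA,II
P19,Other,29,100,L. F1/F2/F3O/striatum,AO,III
P20,Other,25,100,L. F1/F2/F3t,DA,II
P21,Other,36,100,L. F2/F3O,OA,II
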
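name,ba,side,x,y,z,network
L_F3op/F3t,44/45,L,-45,18,27,I
L_IPS,7/39/40,L,-21,-72,51,I
R_LPMC,6/8,R,30,3,45,I
R_F3op/F3t,44/45,R,33,18,24,I
pre-SMA,6/8,M,9,24,51,I
R_pSTG/MTG,22/21,R,60,-57,3,I
L_LPMC,6/8,L,-48,3,42,II
L_AG,39,L,-33,-60,18,II
LG,18,M,-3,-69,6,II
Cerebellar_nuclei,,M,-3,-51,-27,II
L_F3t,45,L,-48,33,6,III
L_F3O,47,L,-36,15,-6,III
L_pSTG/MTG,22/21,L,-57,-48,0,III
L_pMTG/ITG,37/19,L,-45,-69,0,III
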
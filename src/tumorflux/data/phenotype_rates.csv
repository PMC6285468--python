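scenario,cell_type,phenotype,mu,q_Glu,q_O2,q_Lac,q_Gln
warburg,Healthy Stromal Cell,Aerobic,1e-6,-0.045,-0.048,,
warburg,Healthy Stromal Cell,Anaerobic,1e-6,-0.45,-3.2e-7,,
warburg,Warburg Tumor Cell,"Aerobic, WN = 0",0.018,-0.078,-0.064,,
warburg,Warburg Tumor Cell,"Aerobic, WN = 2",0.018,-0.183,-0.052,,
warburg,Warburg Tumor Cell,"Aerobic, WN = 10",0.018,-0.394,-0.0266,,
warburg,Warburg Tumor Cell,"Aerobic, WN = 34",0.018,-0.573,-0.006,,
warburg,Warburg Tumor Cell,Anaerobic,1e-6,-0.45,-3.2e-7,,
reverse_warburg,Hijacked Stromal Cell,Aerobic,1e-6,-0.45,-3.2e-7,0.45,
reverse_warburg,Hijacked Stromal Cell,Anaerobic,1e-6,-0.45,-3.2e-7,0.45,
reverse_warburg,Reverse Warburg Tumor Cell,"Aerobic, WN = 2",0.018,-0.183,-0.052,0.117,
reverse_warburg,Reverse Warburg Tumor Cell,"Aerobic, RW",0.018,-6.72e-3,-0.073,-0.079,
reverse_warburg,Reverse Warburg Tumor Cell,Hypoglycemic,1e-6,-3.73e-7,-0.053,-0.05,
reverse_warburg,Reverse Warburg Tumor Cell,Anaerobic,1e-6,-0.45,-3.2e-7,0.45,
glutamine,Healthy Stromal Cell,Aerobic,1e-6,-0.045,-0.048,,
glutamine,Healthy Stromal Cell,Anaerobic,1e-6,-0.45,-3.2e-7,,
glutamine,Glutamine-addicted Tumor Cell,Aerobic,0.018,-0.122,-0.059,,-0.03
glutamine,Glutamine-addicted Tumor Cell,Anaerobic,1e-6,-1.55e-4,-0.053,,-0.054
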
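wavenumber,assignment,reference
1743.65,Ester carbonyl group C=O of triglycerides,ref058
1681.93,"Succinic acid (pure solid form); Amide I, beta-turns","ref044; ref059"
1639.49,Amide I,ref041
1573.91,C=N adenine,ref041
1485.19,C8-H coupled with a ring vibration of guanine,ref041
1442.75,delta(CH) of pectin,ref045
1396.46,Symmetric CH3 bending of the methyl groups of proteins,ref041
1338.6,In-plane C-O stretching vibration combined with the ring stretch of phenyl,ref041
1141.86,Phosphate and oligosaccharides; oligosaccharide C-O bond in hydroxyl group,ref041
1033.84,Glucomannan,ref042
945.119,Xyloglucan,ref043
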
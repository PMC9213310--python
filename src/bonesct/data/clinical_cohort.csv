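case,lesion_type,region,mad,md,dsc,rmsd
P1,mixed,bone,102,34,0.81,2.70
P2,mixed,bone,146,23,0.86,2.54
P3,osteoblastic,bone,132,-26,0.74,1.74
P4,osteolytic,bone,96,-47,0.85,1.38
P5,osteolytic,bone,77,29,0.88,1.67
P6,osteoblastic,bone,154,119,0.90,1.90
P7,osteoblastic,bone,136,-98,0.89,2.11
P8,osteolytic,bone,109,87,0.9,1.76
P9,osteoblastic,bone,95,7,0.85,2.65
P1,mixed,lesion,94,-64,0.56,4.93
P2,mixed,lesion,143,-55,0.86,2.86
P3,osteoblastic,lesion,166,101,0.82,2.08
P4,osteolytic,lesion,188,100,0.74,1.42
P5,osteolytic,lesion,27,12,0.77,0.75
P6,osteoblastic,lesion,235,-229,0.96,0.89
P7,osteoblastic,lesion,81,29,0.99,2.08
P8,osteolytic,lesion,108,-51,0.60,3.87
P9,osteoblastic,lesion,149,-123,0.49,7.30
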
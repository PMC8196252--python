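species,layer,neurons_per_mm2
human_temporal,L1,1958
human_temporal,L2/3,27514
human_temporal,L4,13158
human_temporal,L5,12738
human_temporal,L6,8052
rat_somatosensory,L1,427
rat_somatosensory,L2/3,28183
rat_somatosensory,L4,13827
rat_somatosensory,L5,20785
rat_somatosensory,L6,36322
mouse_barrel,L1,1258
mouse_barrel,L2/3,32347
mouse_barrel,L4,37723
mouse_barrel,L5,19286
mouse_barrel,L6,55063
macaque_visual,L1,600
macaque_visual,L2/3,56100
macaque_visual,L4,90300
macaque_visual,L5,24800
macaque_visual,L6,30100
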
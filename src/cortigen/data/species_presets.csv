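species,C_M,C_6,C_5,C_4,C_3,C_2,P_M,P_6,P_5,P_4,P_3,T_SYM
human_temporal,0.16,0.1,0.2,0.3,0.5,0.7,0.7,0.65,0.55,0.5,0.3,65
rat_somatosensory,0.08,0.2,0.2,0.3,0.5,0.6,0.55,0.6,0.7,0.5,0.5,65
mouse_barrel,0.14,0.3,0.2,0.5,0.5,0.4,0.45,0.6,0.5,0.4,0.5,65
macaque_visual,0.11,0.2,0.2,0.5,0.4,0.5,0.6,0.4,0.2,0.5,0.5,65
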
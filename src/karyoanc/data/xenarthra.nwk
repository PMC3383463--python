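(((((Bradypus_torquatus,(Bradypus_variegatus,Bradypus_tridactylus)BvarBtri)Bradypus,(Choloepus_hoffmanni,Choloepus_didactylus)Choloepus)Folivora,Tamandua_tetradactyla)Pilosa,(Dasypus_novemcinctus,Euphractus_sexcinctus)Cingulata)Xenarthra,AEK)Eutheria;
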
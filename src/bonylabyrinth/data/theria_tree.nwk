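(Didelphis,(Zhelestid,(Ukhaatherium,((Kulbeckia,Zalambdalestes)E,((Orycteropus,(Macroscelides,(Chrysochloris,Hemicentetes)I)H,(Elephantimorpha,(Procavia,Trichechus)K)J)G,Dasypus,(((Atelerix,Sorex)Y,(((Bathygenys,(Sus,(Tursiops,Balaenopteridae)R)Q)P,Equus)O,(((Canis,Eumetopias)U,Felis)T,Manis)S,(Pteropus,(Nycteris,(Rhinolophus,Tadarida)X)W)V)N)M,(((Cavia,Mus)b,(Lepus,Sylvilagus)c)a,(Cynocephalus,(Homo,Macaca)e)d,Tupaia)Z)L)F)D)C)B)A;
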
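((((S.lamarcki,S.kraussi)Serpulidae,(P.dumerilii,(C.teleta,H.robusta)))Annelida,(((C.gigas,P.fucata)Bivalvia,((L.gigantea,N.fuscoviridis)Lottiidae,P.vulgata)Gastropoda)Mollusca,L.anatina)Molbra)Lophotrochozoa);
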
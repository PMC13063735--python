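(zebrafish:429,(coelacanth:413,(frog:352,((chicken:280,lizard:280)Sauropsida:39,(platypus:180,(opossum:160,(elephant:99,armadillo:99,((dog:78,cow:78)Laurasiatheria:16,((mouse:12,rat:12)Rodentia:75,(marmoset:43,(macaque:29,(chimp:6,human:6)Hominini:23)Catarrhini:14)Simiiformes:44)Euarchontoglires:7)Boreoeutheria:5)Eutheria:61)Theria:20)Mammalia:139)Amniota:33)Tetrapoda:61)Sarcopterygii:16)Vertebrata;
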
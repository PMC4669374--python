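analyte,hydrocarbon,dose_mg_per_kg,rs,letters
dehydrogenases,naphthalene,1000,0.929,c
dehydrogenases,naphthalene,2000,0.847,b
dehydrogenases,naphthalene,4000,0.687,a
dehydrogenases,phenanthrene,1000,0.700,c
dehydrogenases,phenanthrene,2000,0.641,b
dehydrogenases,phenanthrene,4000,0.427,a
dehydrogenases,anthracene,1000,0.956,b
dehydrogenases,anthracene,2000,0.942,b
dehydrogenases,anthracene,4000,0.839,a
dehydrogenases,pyrene,1000,0.981,c
dehydrogenases,pyrene,2000,0.859,b
dehydrogenases,pyrene,4000,0.709,a
urease,naphthalene,1000,0.571,c
urease,naphthalene,2000,0.483,b
urease,naphthalene,4000,0.254,a
urease,phenanthrene,1000,0.164,b
urease,phenanthrene,2000,0.091,a
urease,phenanthrene,4000,0.065,a
urease,anthracene,1000,0.539,c
urease,anthracene,2000,0.399,b
urease,anthracene,4000,0.274,a
urease,pyrene,1000,0.672,c
urease,pyrene,2000,0.419,b
urease,pyrene,4000,0.260,a
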
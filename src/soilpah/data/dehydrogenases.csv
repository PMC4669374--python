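analyte,hydrocarbon,dose_mg_per_kg,value,letters
dehydrogenases,naphthalene,0,8.62,c
dehydrogenases,naphthalene,1000,8.93,c
dehydrogenases,naphthalene,2000,7.25,b
dehydrogenases,naphthalene,4000,6.21,a
dehydrogenases,phenanthrene,0,8.62,c
dehydrogenases,phenanthrene,1000,7.10,b
dehydrogenases,phenanthrene,2000,6.73,b
dehydrogenases,phenanthrene,4000,5.15,a
dehydrogenases,anthracene,0,8.63,b
dehydrogenases,anthracene,1000,8.73,b
dehydrogenases,anthracene,2000,8.37,ab
dehydrogenases,anthracene,4000,7.87,a
dehydrogenases,pyrene,0,8.63,c
dehydrogenases,pyrene,1000,8.62,c
dehydrogenases,pyrene,2000,7.98,b
dehydrogenases,pyrene,4000,7.16,a
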
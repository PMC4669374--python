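analyte,hydrocarbon,dose_mg_per_kg,value,letters
urease,naphthalene,0,2.76,c
urease,naphthalene,1000,2.00,b
urease,naphthalene,2000,1.80,b
urease,naphthalene,4000,1.11,a
urease,phenanthrene,0,2.76,d
urease,phenanthrene,1000,2.43,c
urease,phenanthrene,2000,1.44,b
urease,phenanthrene,4000,1.06,a
urease,anthracene,0,2.76,d
urease,anthracene,1000,1.93,c
urease,anthracene,2000,1.57,b
urease,anthracene,4000,1.18,a
urease,pyrene,0,2.76,d
urease,pyrene,1000,2.22,c
urease,pyrene,2000,1.63,b
urease,pyrene,4000,1.14,a
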
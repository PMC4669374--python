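analyte,hydrocarbon,dose_mg_per_kg,value,letters
organotrophic_count,naphthalene,0,18.25,a
organotrophic_count,naphthalene,1000,23.25,b
organotrophic_count,naphthalene,2000,34.22,c
organotrophic_count,naphthalene,4000,44.36,d
organotrophic_count,phenanthrene,0,18.25,a
organotrophic_count,phenanthrene,1000,22.47,b
organotrophic_count,phenanthrene,2000,27.67,bc
organotrophic_count,phenanthrene,4000,31.12,c
organotrophic_count,anthracene,0,18.25,a
organotrophic_count,anthracene,1000,32.25,b
organotrophic_count,anthracene,2000,39.48,c
organotrophic_count,anthracene,4000,63.70,d
organotrophic_count,pyrene,0,18.25,a
organotrophic_count,pyrene,1000,35.72,b
organotrophic_count,pyrene,2000,50.68,c
organotrophic_count,pyrene,4000,52.79,c
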
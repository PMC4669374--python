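table,hydrocarbon,statistic,value
organotrophic_count,naphthalene,average,30.02
organotrophic_count,phenanthrene,average,24.87
organotrophic_count,anthracene,average,38.42
organotrophic_count,pyrene,average,39.36
organotrophic_count,naphthalene,r,0.98
organotrophic_count,phenanthrene,r,0.96
organotrophic_count,anthracene,r,0.99
organotrophic_count,pyrene,r,0.88
dehydrogenases,naphthalene,average,7.75
dehydrogenases,phenanthrene,average,6.90
dehydrogenases,anthracene,average,8.40
dehydrogenases,pyrene,average,8.10
dehydrogenases,naphthalene,r,-0.93
dehydrogenases,phenanthrene,r,-0.98
dehydrogenases,anthracene,r,-0.94
dehydrogenases,pyrene,r,-0.97
urease,naphthalene,average,1.91
urease,phenanthrene,average,1.92
urease,anthracene,average,1.86
urease,pyrene,average,1.93
urease,naphthalene,r,-0.97
urease,phenanthrene,r,-0.95
urease,anthracene,r,-0.93
urease,pyrene,r,-0.98
rs_dehydrogenases,naphthalene,average,0.821
rs_dehydrogenases,phenanthrene,average,0.589
rs_dehydrogenases,anthracene,average,0.912
rs_dehydrogenases,pyrene,average,0.849
rs_dehydrogenases,naphthalene,r,-0.99
rs_dehydrogenases,phenanthrene,r,-0.99
rs_dehydrogenases,anthracene,r,-0.97
rs_dehydrogenases,pyrene,r,-0.99
rs_urease,naphthalene,average,0.436
rs_urease,phenanthrene,average,0.106
rs_urease,anthracene,average,0.404
rs_urease,pyrene,average,0.450
rs_urease,naphthalene,r,-0.99
rs_urease,phenanthrene,r,-0.89
rs_urease,anthracene,r,-0.97
rs_urease,pyrene,r,-0.94
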
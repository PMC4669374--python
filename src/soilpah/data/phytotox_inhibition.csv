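species,hydrocarbon,metric,value,letters
Lepidium_sativum,naphthalene,sg,20.0,a
Lepidium_sativum,phenanthrene,sg,10.0,abc
Lepidium_sativum,anthracene,sg,0.0,c
Lepidium_sativum,pyrene,sg,16.6,ab
Sorghum_saccharatum,naphthalene,sg,0.0,c
Sorghum_saccharatum,phenanthrene,sg,0.0,c
Sorghum_saccharatum,anthracene,sg,6.6,abc
Sorghum_saccharatum,pyrene,sg,0.0,c
Sinapis_alba,naphthalene,sg,6.6,abc
Sinapis_alba,phenanthrene,sg,0.0,c
Sinapis_alba,anthracene,sg,3.3,bc
Sinapis_alba,pyrene,sg,16.6,ab
Lepidium_sativum,naphthalene,ri,16.2,cd
Lepidium_sativum,phenanthrene,ri,22.5,abc
Lepidium_sativum,anthracene,ri,16.4,cd
Lepidium_sativum,pyrene,ri,15.9,cd
Sorghum_saccharatum,naphthalene,ri,9.3,cd
Sorghum_saccharatum,phenanthrene,ri,-1.25,d
Sorghum_saccharatum,anthracene,ri,-22.7,e
Sorghum_saccharatum,pyrene,ri,-23.2,e
Sinapis_alba,naphthalene,ri,21.8,bc
Sinapis_alba,phenanthrene,ri,40.4,a
Sinapis_alba,anthracene,ri,37.9,ab
Sinapis_alba,pyrene,ri,11.9,cd
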
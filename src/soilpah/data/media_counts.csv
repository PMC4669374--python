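microorganism,treatment,value,sd,unit
bacteria,control,115,18,1e7 cfu kg-1 DM
bacteria,naphthalene,38,4,1e7 cfu kg-1 DM
bacteria,phenanthrene,90,9,1e7 cfu kg-1 DM
bacteria,anthracene,154,14,1e7 cfu kg-1 DM
bacteria,pyrene,43,7,1e7 cfu kg-1 DM
staphylococci,control,240,22,1e3 cfu kg-1 DM
staphylococci,naphthalene,430,25,1e3 cfu kg-1 DM
staphylococci,phenanthrene,250,15,1e3 cfu kg-1 DM
staphylococci,anthracene,450,21,1e3 cfu kg-1 DM
staphylococci,pyrene,520,32,1e3 cfu kg-1 DM
molds,control,9,2,1e3 cfu kg-1 DM
molds,naphthalene,9,1,1e3 cfu kg-1 DM
molds,phenanthrene,8,2,1e3 cfu kg-1 DM
molds,anthracene,36,7,1e3 cfu kg-1 DM
molds,pyrene,25,4,1e3 cfu kg-1 DM
enterobacteriaceae,control,9,3,1e3 cfu kg-1 DM
enterobacteriaceae,naphthalene,3200,10,1e3 cfu kg-1 DM
enterobacteriaceae,phenanthrene,3300,21,1e3 cfu kg-1 DM
enterobacteriaceae,anthracene,1600,8,1e3 cfu kg-1 DM
enterobacteriaceae,pyrene,6200,20,1e3 cfu kg-1 DM
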
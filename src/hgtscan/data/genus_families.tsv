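genus	family
Halomonas	Halomonadaceae
Chromohalobacter	Halomonadaceae
Cobetia	Halomonadaceae
Kushneria	Halomonadaceae
Modicisalibacter	Halomonadaceae
Salinicola	Halomonadaceae
Zymobacter	Halomonadaceae
Carnimonas	Halomonadaceae
Halotalea	Halomonadaceae
Aidingimonas	Halomonadaceae
Idiomarina	Idiomarinaceae
Gracilimonas	Balneolaceae
Burkholderia	Burkholderiaceae
Pseudomonas	Pseudomonadaceae
Paraglaciecola	Alteromonadaceae
Stenotrophomonas	Xanthomonadaceae
Pseudoxanthomonas	Xanthomonadaceae
Sphingopyxis	Sphingomonadaceae
Hyphomonas	Hyphomonadaceae
Thialkalivibrio	Ectothiorhodospiraceae
Thioalkalivibrio	Ectothiorhodospiraceae
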
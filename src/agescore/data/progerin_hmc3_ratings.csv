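marker,category,control,day3,day7,day14
gamma_h2ax,primary,0,1,1,1
h3k9me3,primary,0,1,1,1
telomere,primary,0,0,0,0
p21,antagonistic,0,0,0,0
p16,antagonistic,0,0,0,0
sa_bgal,antagonistic,0,1,1,1
il6,antagonistic,0,1,1,1
il8,antagonistic,0,1,1,1
lamin_b1,antagonistic,0,1,1,1
nucleus_area,antagonistic,0,0,0,1
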
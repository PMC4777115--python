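sample	role	chr5:41014230	chr5:41014231	chr5:41055619	chr6:24951743	chr37:30832376	chr12:14853811	chr20:39951727
offspring	affected_offspring	T/T	T/T	C/C	T/T	T/T	T/T	T/T
sire	healthy_sire	G/T	C/T	C/G	G/T	C/T	C/T	G/T
dam	healthy_dam	G/T	C/T	C/G	G/T	C/T	C/T	G/T
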
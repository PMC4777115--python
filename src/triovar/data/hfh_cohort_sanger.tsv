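sample	phenotype	chr5:41014230	chr5:41014231	chr5:41055619	chr6:24951743	chr37:30832376	chr12:14853811	chr20:39951727
case1	case	T/T	T/T	C/C	G/T	C/T	C/C	T/T
case2	case	T/T	T/T	C/C	G/T	C/C	C/C	G/G
case3	case	T/T	T/T	C/C	G/T	C/T	C/T	G/G
case4	case	T/T	T/T	C/C	T/T	C/C	T/T	G/G
case5	case	T/T	T/T	C/C	G/T	C/T	C/T	T/T
case6	case	T/T	T/T	C/C	G/G	C/T	T/T	T/T
case7	case	T/T	T/T	C/C	G/G	C/T	C/T	G/G
case8	case	T/T	T/T	C/C	G/G	C/T	C/T	G/T
control1	control	G/G	C/C	G/G	G/T	T/T	C/T	T/T
control2	control	G/G	C/C	G/G	G/G	T/T	C/T	G/G
control3	control	G/G	C/C	G/G	G/T	T/T	C/T	G/G
control4	control	G/G	C/C	G/G	G/G	C/T	C/C	G/G
control5	control	G/T	C/T	C/G	G/T	C/T	C/T	G/G
control6	control	G/T	C/T	G/G	G/T	C/T	C/T	G/T
control7	control	G/G	C/C	G/G	G/G	C/T	C/C	G/G
control8	control	G/G	C/C	G/G	G/G	C/T	C/C	G/G
control9	control	G/T	C/T	C/G	G/G	T/T	C/C	G/T
control10	control	G/G	C/C	G/G	G/G	C/T	C/C	G/T
control11	control	G/T	C/T	C/G	G/T	C/C	C/T	G/G
control12	control	G/G	C/C	G/G	G/T	C/T	C/T	G/G
control13	control	G/G	C/C	G/G	G/T	C/C	C/T	G/G
control14	control	G/G	C/C	G/G	G/G	C/T	C/C	G/G
control15	control	G/G	C/C	G/G	G/T	C/T	C/T	G/G
control16	control	G/G	C/C	G/G	G/T	C/C	C/T	G/T
CanFam3.1	reference	G/G	C/C	G/G	G/G	C/C	C/C	G/G
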
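Empirical amino-acid replacement matrices, PAML dat layout: 19 rows of
lower-triangle exchangeabilities (order ARNDCQEGHILKMFPSTWYV) followed by
the 20 stationary frequencies. Values are the published matrices of the
respective authors (Dayhoff et al.; Jones/Taylor/Thornton JTT and
JTT-DCMut; Le & Gascuel LG; Whelan & Goldman WAG; Henikoff Blosum62;
Adachi & Hasegawa mtREV24; Abascal et al. mtArt; Rota-Stabelli et al.
mtZoa; Dimmic et al. rtREV; Mueller & Vingron VT; Nickle et al. HIVb/HIVw;
Kosiol & Goldman DCMut; Dang et al. FLU; Yang et al. mtMAM; Adachi & Waddell
cpREV), as redistributed by the phangorn R package (v2.12.1).
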
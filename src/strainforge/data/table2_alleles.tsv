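coordinate	wMel	DGRP335	DGRP338	CantonS	wMelPop
12863	T	C	C	T	T
52597	TGCGATAAT	TGCGATAAT	TGCGATAAT	-	-
208096	C	T	T	C	C
297946	C	C	C	T	T
387634	G	A	A	G	G
432815	G	A	A	G	G
1144825	TGTTGGTTT	TGTTGGTTT	TGTTGGTTT	-	-
1254084	G	A	A	G	G
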
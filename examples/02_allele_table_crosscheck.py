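"""The printed allele-table worked example.

Eight sequence variants separate the wild-derived donor-strain isolates
(wMelCS/DGRP335, wMelCS/DGRP338) from the pathogenic strain wMelPop; at
every one of those sites the long-standing lab stock (wMelCS/Canton-S) is
identical to wMelPop.  Counting pairwise differences from the table makes
that relationship explicit: the pathogen is genomically indistinguishable
from the lab-stock donor at all eight loci.
"""

from strainforge.variants import allele_table_differences, load_allele_table

table = load_allele_table()
print(table.to_string(index=False))
print()
for a, b in (("DGRP335", "wMelPop"), ("DGRP338", "wMelPop"),
             ("CantonS", "wMelPop"), ("DGRP335", "DGRP338")):
    diffs = allele_table_differences(table, a, b)
    classes = sorted(d.cls for d in diffs)
    print(f"{a:>8s} vs {b}: {len(diffs)} difference(s) {classes}")
# 8 differences for each DGRP isolate vs the pathogen, 0 for the lab stock:
# the pathogenic strain arose from within the lab-stock lineage.
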
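"""Scan a sequence for telomere-like (TG1-3)n tracts on both strands.

Plants a 35 bp telomeric tract in random background and recovers it;
tracts this long outside telomeres are candidate de novo telomere
seeds.
"""

import numpy as np

from istex import filter_hits, generate_tract, revcomp, scan_tracts, tel_tract

rng = np.random.default_rng(11)
background = "".join(rng.choice(list("ACGTAC"), size=10_000))
tract = generate_tract(tel_tract(), 35, rng)[:35]
seq = background[:4000] + "A" + tract + "A" + background[4037:]
seq = seq[:7000] + "G" + revcomp(tract)[:30] + "G" + seq[7032:]

hits = scan_tracts(seq, min_len=12)
for h in hits[:5]:
    print(f"{h.start:>5}-{h.end:<5} {h.strand}  {h.length:>2} bp  {h.tract_seq}")
plus_only = filter_hits(hits, orientation="+")
print(f"\n{len(hits)} tracts >= 12 bp total; {len(plus_only)} on the + strand")
print("(the longest hit is the planted tract; minus-strand hits are")
print(" G-rich tracts reading toward the other end of the molecule)")
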
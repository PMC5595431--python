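"""Tokenize and classify telomeric repeat sequence under the three grammars.

Wild-type telomerase adds imperfect 5'-(TG)0-6 TGGGTGTG (G)0-1-3'
repeats; the template mutant adds 5'-[(TG)0-4 TGG]n ATTTGG-3'. The base
A and G-runs of three are the hard diagnostics separating them.
"""

import numpy as np

from istex import classify_segment, generate_tract, tm_unit, tokenize, wt_unit

seq = "TGTGGATTTGG"
res = tokenize(seq, tm_unit())
print(f"{seq} under the mutant grammar: "
      f"{[t.text for t in res.tokens]} (fully parsed: {res.fully_parsed})")

rng = np.random.default_rng(3)
mutant_tract = generate_tract(tm_unit(), 40, rng)
wt_repeat = generate_tract(wt_unit(), 20, rng)
for s in (mutant_tract, wt_repeat, "TGTGG"):
    print(f"{s:<45} -> {classify_segment(s).value}")
print("(MUTANT = telomerase-added divergence; WILDTYPE = recombination or")
print(" cloning artifact; short segments compatible with both are AMBIGUOUS)")
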
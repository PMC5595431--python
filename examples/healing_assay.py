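"""Telomere-addition (healing) frequencies from plating counts.

Computes both frequency readouts for a telomeric-seed strain and its
pif1-m2 reference, and the Pif1-activity ratio.
"""

from istex import (
    PlatingCount,
    addition_frequency,
    addition_frequency_alt,
    normalize_to_pif1,
    summarize_replicates,
)

replicates = [
    PlatingCount("TG34", "PIF1", 34, pre_gal=210, post_gal=180, resistant=58),
    PlatingCount("TG34", "PIF1", 34, pre_gal=195, post_gal=170, resistant=49),
    PlatingCount("TG34", "PIF1", 34, pre_gal=220, post_gal=200, resistant=67),
]
reference = PlatingCount("TG34-m2", "pif1-m2", 34,
                         pre_gal=205, post_gal=185, resistant=66)

freqs = [addition_frequency(c) for c in replicates]
mean, sd, n = summarize_replicates(freqs)
ref = addition_frequency(reference)
print(f"standard method:    {mean:.1f} ± {sd:.1f} % (n = {n})")
print(f"alternative method: {addition_frequency_alt(replicates[0]):.1f} % "
      "(first replicate)")
print(f"pif1-m2 reference:  {ref:.1f} %")
print(f"normalized ratio:   {normalize_to_pif1(mean, ref):.2f}")
print("(a ratio near 1 means Pif1 no longer suppresses telomere addition")
print(" at this seed length - the end behaves as a short telomere)")
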
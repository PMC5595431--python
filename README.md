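# istex — telomere extension analysis at nucleotide resolution

Budding-yeast cells must treat a DNA double-strand break and a critically
short telomere — two structurally similar DNA ends — in opposite ways:
repair one, elongate the other. The Pif1 helicase enforces this decision by
evicting telomerase from ends carrying too little telomeric `(TG1-3)n`
sequence, producing a sharp length threshold (~40 bp at natural chromosome
ends) below which telomerase extension collapses.

This package implements the computational side of the single-telomere
extension (STEX/iSTEX) family of assays, in which telomerase is switched on
for one cell cycle and individual telomere molecules are cloned and
sequenced. Because a template-mutant telomerase (*tlc1-tm*) adds
`5'-[(TG)0-4 TGG]n ATTTGG-3'` repeats instead of the wild-type
`5'-(TG)0-6 TGGGTGTG (G)0-1-3'`, newly added sequence is distinguishable
from pre-existing repeats at single-base resolution.

For each cloned telomere *i* the pipeline measures the undiverged length
`L_i` (bases matching the shared clonal sequence before the divergence
point) and the extension indicator `X_i` (mutant sequence present in the
divergent suffix). The central statistic is the 2×2 table of extended /
unextended clones below a threshold *t* versus an upper comparison window,
evaluated with a two-sided Fisher's exact test (point-probability rule,
log-factorial hypergeometric implementation), after excluding clones whose
only divergence is wild type (telomerase-independent events). A changepoint
scan over candidate thresholds locates the data-driven transition.

## What's in the box

| module | purpose |
| --- | --- |
| `istex.grammar` | the three repeat grammars: tokenization, sampling, mutant/wild-type segment classification |
| `istex.divergence` | anchor trimming, two-pass consensus, windowed divergence calling, per-clone calls |
| `istex.stats` | contingency tables, exact test, percent summaries, threshold scan, sorted per-clone table |
| `istex.simulate` | stochastic simulator of length-dependent, Pif1-gated extension with per-clone ground truth |
| `istex.healing` | genetic telomere-addition assay frequencies and pif1-m2 normalization |
| `istex.tracts` | strand-aware scanner for telomere-like tracts in arbitrary DNA |
| `istex.io` / `istex.cli` | FASTA/TSV/JSON I/O and a thin `istex` command-line interface |

## Worked example

```python
from istex import (AnchorSpec, LengthWindow, SimConfig, TelomereClone,
                   extension_table, fisher_exact, percent_extended,
                   process_experiment, scan_threshold, simulate_experiment)

cfg = SimConfig(n_clones=200, seed=7)              # wild-type PIF1 cells
exp = simulate_experiment(cfg)
clones = [TelomereClone(c.clone_id, cfg.locus_id, cfg.genotype, c.seq)
          for c in exp.clones]
calls, _ = process_experiment(clones, AnchorSpec(cfg.locus_id, cfg.anchor_seq))

tab = extension_table(calls, 40, LengthWindow(40, 80))
print(percent_extended(tab.n11, tab.n11 + tab.n12))   # 3.9   (% extended < 40 bp)
print(percent_extended(tab.n21, tab.n21 + tab.n22))   # 53.7  (% extended 40-80 bp)
print(fisher_exact(tab).p_two_sided)                  # 1.31e-10
print(scan_threshold(calls).best_threshold)           # 40
```

Extension is efficient in the 40–80 bp window (53.7%) and collapses below
40 bp (3.9%); the exact test rejects independence decisively and the
threshold scan recovers the simulated 40 bp transition. On the published
V-R window counts the same machinery gives 2/32 = 6.3% extended below 44 bp
versus 65/136 = 47.8% in the 44–86 bp window (p = 5.0e-06); see
`examples/published_window_test.py`.

The `examples/` directory holds one short narrative script per capability
(simulation + calling, threshold statistics, published window counts,
healing-assay frequencies, tract scanning, grammar tour); each prints the
numbers it computes and a line on what they mean. The same stages are
available from the shell:

```sh
istex simulate --outdir out --seed 7
istex call --clones out/istex_clones.fasta --anchors anchors.fasta -o out/calls.tsv
istex stats --calls out/calls.tsv --threshold 40 --scan -o out/summary.json
```

## Documentation

`docs/methods.md` describes the models, parameter defaults, numerical
choices and known limitations.
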
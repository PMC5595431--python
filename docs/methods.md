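# Methods

## The measurement problem

In a single-telomere extension experiment, telomerase is active for one
cell cycle in a clonal population whose telomeres have eroded to
heterogeneous lengths. Individual telomere molecules are then amplified,
cloned and sequenced. Every clone shares its proximal (centromere-side)
sequence with the clonal baseline; anything distal to the *divergence
point* is new: telomerase-added repeats, recombination products, or
amplification/cloning/sequencing artifacts. Because the experiment uses a
template-mutant telomerase whose repeats contain the base A (in the
terminator `ATTTGG`) while wild-type G-strand telomeric DNA contains none,
telomerase-dependent divergence is separable from telomerase-independent
divergence.

All sequences are handled as the G-rich strand read 5'→3' toward the
chromosome end; C-strand input must be reverse-complemented by the caller.
Coordinates are 1-based inclusive; position 1 is the first base after the
subtelomeric anchor. BED-like scanner output alone uses 0-based half-open
coordinates.

## Repeat grammars

Three grammars describe telomeric sequence (`istex.grammar`):

* **TEL_TRACT** — generic heterogeneous tract: any string over {T, G} whose
  maximal G-runs are ≤ `g_max` (default 3) and maximal T-runs ≤ `t_max`
  (default 4). Strict `(TG1-3)n` would forbid TT, but natural tracts carry
  short T-runs; the permissive bound avoids false divergence calls inside
  baseline sequence.
* **WT_UNIT** — wild-type telomerase repeat `(TG)a TGGGTGTG (G)b`,
  a ∈ 0..6, b ∈ 0..1.
* **TM_UNIT** — template-mutant blocks `(TG)a TGG` (a ∈ 0..4) closed by the
  terminator `ATTTGG`. The tract sampler always emits the terminator, as
  the mutant template does.

Tokenization is complete-prefix-optimal: a dynamic program over unit
lengths guarantees the parsed prefix is as long as any tokenization can
make it; among optimal tokenizations, longer units are preferred from the
5' end (only `parsed_len` matters downstream). TEL_TRACT, being
run-bounded, is parsed by linear run scanning and tokenized into maximal
homopolymer runs.

### Segment classification

Telomerase repeats are imperfect in vivo, so classification leans on two
hard diagnostics rather than exact unit structure: the base **A** occurs
only in the mutant terminator (full `ATTTGG` anywhere, or a truncated
terminator carrying its A at the segment's 3' end, where sequencing simply
stopped), and **G-runs of three** are never produced by mutant blocks —
including across block/terminator junctions. Both present ⇒ MIXED; A-free,
GGG-free segments of at least `min_call_len` (default 6 bp, one terminator
length) that parse only as a generic tract ⇒ WILDTYPE; segments compatible
with both grammars (every block string is also a valid tract) are
AMBIGUOUS by default — a config switch (`tm_block_parse_calls_mutant`)
makes them MUTANT for analyses that prefer recall over precision. Segments
shorter than `min_call_len` without hard evidence are AMBIGUOUS and never
count as events. `require_full_terminator=True` disables the
truncated-terminator rule.

## Divergence calling

Per locus (`istex.divergence`):

1. **Anchor trimming.** The locus-specific subtelomeric anchor (≥ 12 bp) is
   slid from the 5' end; the first placement with ≤ `max_anchor_mismatch`
   (default 2) substitutions wins. Clones without an acceptable match are
   rejected and logged, not fatal.
2. **Reference.** Either a known reference sequence, or a two-pass
   positional-majority consensus: pass 1 takes the per-position majority
   over all clones (ties → base of the longest contributing clone, then
   alphabetical); pass 2 rebuilds the majority from each clone's
   pre-divergence prefix only, so newly added sequence cannot pollute the
   distal consensus. The clonal baseline assumption makes positional
   majority well-posed.
3. **Divergence point.** Comparisons are strictly positional (no gapped
   alignment — an indel manifests as divergence, matching the "stops
   aligning" reading). Positions beyond the reference count as mismatches;
   positions beyond the clone truncate the window. The divergence point is
   the first mismatch whose following `window_w` bp contain ≥ `window_k`
   mismatches; sparser mismatches are attributed to sequencing/PCR error.
   A clone that is a clean prefix of the reference has eroded, not
   diverged: it is unextended with undiverged length equal to its own
   length.
4. **Suffix split.** The divergent suffix is split at the first terminator
   evidence, pulled backward through any contiguous run of mutant blocks
   (dynamic program): that part is mutant (red); whatever precedes it is
   wild-type divergence (grey). A suffix with no terminator evidence is
   classified whole: WILDTYPE ⇒ the clone is *excluded* from extension
   statistics (telomerase-independent event); AMBIGUOUS ⇒ recorded, no
   event.

### Window parameters

Defaults are `window_w=12`, `window_k=3`. The choice is driven by the
sequence context: mutant and wild-type tracts are both near-periodic TG, so
positional identity beyond a true divergence point is only ~50%, and a
short dense window (e.g. 4-of-6) typically fires several bases late —
measured on simulated data at 0.2%/bp error it left only ~55% of calls
within ±3 bp of truth, versus ~98% for 3-of-12 (extension-flag accuracy
~99%). Three mismatches within 12 bp from independent sequencing errors is
vanishingly rare below 1%/bp error, so isolated errors are still ignored.
With error-free data `window_k=1` pinpoints the first mismatch exactly and
is the recommended strict setting.

## Threshold statistics

Clones surviving exclusion are cross-tabulated by extension status below a
threshold *t* versus an upper window \[t, hi\] (`extension_table`; clones
above `hi` are omitted, mixed-divergence clones count as extended — they
carry mutant sequence — with a documented alternative of dropping them).
`fisher_exact` implements the two-sided test from first principles with
log-factorials: p is the sum of hypergeometric point probabilities, over
all tables with the observed margins, that do not exceed the observed
table's probability (relative tolerance 1e-9 for ties). This is the
classical point-probability rule, stated explicitly because
implementations differ (it is not p-doubling). Degenerate margins give
p = 1; the odds ratio uses the Haldane 0.5 correction when a cell is zero.
Percentages are printed to one decimal, rounded half-up.

`scan_threshold` formalizes the choice of threshold, which upstream
analyses made by inspection. Each candidate (every observed undiverged
length) is scored by the exact test on two symmetric local windows,
\[t−30, t) versus \[t, t+30\] by default: the extension probability also
*declines* smoothly with length, and an unbounded below/above split
confounds that trend with the discontinuity (on simulated data it
recovered the true threshold within ±6 bp in only ~78% of seeds at n=150,
versus ~90% for local windows). Candidates need `min_group` (default 10)
clones in both windows and a below-window rate lower than the upper
window's — the sought transition is inefficiency *below* the threshold.
The reported threshold is the smallest candidate whose p lies within a
factor of two of the minimum: p-values that close are not distinguishable,
and changepoint scans on a declining background overshoot, so the small
edge of the near-optimal plateau is the better point estimate. The number
of candidates tested is reported as a Bonferroni count; no correction is
applied to the primary window tests, which are single pre-specified
comparisons.

`compare_genotypes` runs the same exact test on extended/unextended counts
below the threshold, wild type versus *pif1-m2*, and errors out when either
genotype has no sub-threshold clones (short telomeres are hard to obtain).

## The simulator

`istex.simulate` generates a single post-induction snapshot with per-clone
ground truth. Components, with defaults and units:

| parameter | default | meaning |
| --- | --- | --- |
| `baseline_mean`, `baseline_sd`, `baseline_min` | 60, 25, 5 bp | truncated-normal eroded-telomere lengths; populates both sides of the threshold |
| `threshold_T` | 40 bp | length below which PIF1 cells extend inefficiently |
| `p_max`, `p_floor`, `L_ref` | 0.55, 0.05, 300 bp | linear extension-probability trend p(L) = p_floor + (p_max − p_floor)·max(0, 1 − L/L_ref) |
| `p_short` | 0.06 | sub-threshold extension probability in PIF1 cells |
| `processivity_cutoff` | 125 bp | below this, more repeat blocks are added per event |
| `mean_units_short`, `mean_units_long` | 5, 2 | geometric (≥ 1) mean mutant blocks per extension |
| `artifact_rate` | 0.05 | probability a distal slice is replaced by fresh wild-type tract (recombination / cloning artifact) |
| `seq_error_rate` | 0.002 /bp | iid substitution errors |
| `n_clones` | 200 | clones per experiment |

Every baseline is a prefix of one sampled master tract, so clones share
their proximal sequence (the clonal assumption the consensus relies on).
For L ≥ T the extension probability follows the declining trend; below T,
PIF1 cells drop to `p_short` while *pif1-m2* cells continue at p(T) — the
minimal model consistent with the known qualitative behavior (extension
probability rises as telomeres shorten; the collapse below ~40 bp is
Pif1-dependent). With these defaults the simulated extension fraction is
~6–10% below 40 bp and ~40–50% in the 40–80 bp window, echoing the
6.3%/47.8% regime observed at the V-R telomere.

Ground truth records, per clone: baseline length, extension and artifact
flags, number of blocks appended, the append position (baseline + 1), and
the **operational divergence position** — the first base at which the
finished (pre-error) clone differs from the master. The two positions can
differ because an appended repeat may coincidentally match the master for
its first bases; no alignment-based caller can recover the append position
in that case, so calls are scored against the operational position.

What the simulator does *not* model: indels (the divergence rule is
positional, and the error channel matches it), PCR amplification bias,
chromatogram noise, cell-cycle or multi-generation dynamics, and any
specific distribution of recombination-tract lengths (the uniform distal
slice is a placeholder). Passing tests therefore demonstrate correctness
of the analysis under these statistical assumptions, not robustness to
alignment-shifting indels or amplification artifacts in real traces.

## Healing assay

`istex.healing` implements the two plating-count readouts: the standard
frequency (α-AA-resistant / post-induction survivors, as percent) and the
alternative (resistant / (pre-induction − sensitive)), with `sensitive`
derived as post − resistant when not supplied. The alternative readout
shows the same threshold with more variability; both are reported side by
side. Normalization divides by the *pif1-m2* reference frequency of the
same DNA end, cancelling cutting efficiency and per-end telomerase
recruitment; pairing is by explicit reference strain in the input table.
Replicates are summarized as mean ± sample (n−1) s.d.; a single replicate
yields NaN s.d., flagged rather than silently zero.

## Tract scanner

`istex.tracts` enumerates all maximal intervals (two-pointer sweep, linear
time; validity is hereditary) whose sequence — or reverse complement,
reported on the − strand — is a valid TEL_TRACT, with `min_len ≥ 8`.
N breaks tracts. "Correct orientation" is a strand filter left to the
caller, since which strand would form the G-rich end depends on the side
of the prospective break; exclusion intervals use a documented
closed-interval overlap rule. Reproducing specific genomic tract
coordinates requires an external genome assembly and is out of scope; an
analysis would run the scanner over a genome FASTA with subtelomeric
regions excluded.

## Numerical and design notes

* Determinism: all randomness flows from numpy `default_rng` seeded by the
  config; identical config ⇒ byte-identical FASTA/TSV output. The pipeline
  writes its resolved config and a SHA-256 config hash next to results.
* The exact-test sum is clamped to 1 when it exceeds 1 − 1e-12 (full-sum
  round-off).
* Consensus ties are resolved deterministically (longest contributor, then
  alphabetical); sorted tables break ties by clone id.
* Problem sizes in the test suite and acceptance script — n=150–200 clones
  per simulated experiment, 20 seeds per property, 10 kb scanner sequences
  — were chosen to match the scale of the real datasets (~170–230 clones
  per locus) while keeping full runs fast.

## Known limitations

* Positional comparison means an early indel (real or PCR-induced) is
  called as divergence; gapped alignment would be an extension.
* The undiverged length slightly overestimates truth when an extension
  begins with bases that coincidentally match the reference; this is
  intrinsic to the assay, not the implementation.
* Consensus mode cannot see past the longest shared baseline; clones
  extending beyond it are divergent from that point by construction. Use
  reference mode when the baseline sequence is known.
* The threshold scan assumes a single transition on a monotone background;
  multiple transitions would need a multi-changepoint extension.
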
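"""Stochastic simulator of length-dependent, Pif1-gated telomere extension.

The simulator emulates a single post-induction snapshot of an inducible
single-telomere-extension experiment: a clonal population whose
telomeres have eroded to heterogeneous lengths, one cell cycle of
template-mutant telomerase activity, then amplification/cloning/
sequencing of individual molecules. Ground truth is recorded per clone
so every downstream stage can be scored.

Model components:

* Baseline lengths are drawn from a truncated normal; every baseline is
  a prefix of one clonal master (TG1-3)n tract, so clones share their
  proximal sequence.
* The per-clone extension probability rises linearly as length falls,
  p(L) = p_floor + (p_max - p_floor) * max(0, 1 - L/L_ref) for L >= T,
  and collapses to a small constant p_short below the threshold T in
  PIF1 cells; in pif1-m2 cells the trend simply continues (p(T)) —
  Pif1 no longer gates short ends.
* Extensions append geometrically many mutant (TG)a TGG blocks closed by
  the ATTTGG terminator; mean block count is higher below the
  processivity cutoff (125 bp), where telomerase acts more processively.
* A small artifact channel replaces a distal slice with fresh,
  independent wild-type tract sequence (telomerase-independent
  divergence: recombination or amplification/cloning error).
* Sequencing/PCR error is iid per-base substitution.

Because the appended mutant sequence can coincidentally match the master
for its first bases, the recorded ground-truth divergence position is
operational: the first position at which the finished (pre-error) clone
differs from the master. The append position (baseline length + 1) is
recorded separately.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grammar import GrammarId, GrammarSpec, generate_tract, tel_tract, tm_unit
from .divergence import PIF1, PIF1_M2

DEFAULT_ANCHORS = {
    # Synthetic subtelomeric anchors (fixed, arbitrary non-telomeric sequence).
    "V-R": "GATCACGCTAAGCTACGATCCTTACAGCAG",
    "VI-R": "CCTAGAGTACGATTCGCAAGTCTAACGGAC",
}


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; defaults describe the study conditions.

    ``threshold_T`` (~40 bp) is the length below which PIF1 cells extend
    inefficiently; ``processivity_cutoff`` (125 bp) switches the mean
    number of mutant repeat blocks appended per event.
    """

    locus_id: str = "V-R"
    genotype: str = PIF1
    n_clones: int = 200
    baseline_mean: float = 60.0
    baseline_sd: float = 25.0
    baseline_min: int = 5
    threshold_T: int = 40
    p_max: float = 0.55
    p_floor: float = 0.05
    p_short: float = 0.06
    L_ref: int = 300
    processivity_cutoff: int = 125
    mean_units_short: float = 5.0
    mean_units_long: float = 2.0
    artifact_rate: float = 0.05
    seq_error_rate: float = 0.002
    anchor_seq: str = DEFAULT_ANCHORS["V-R"]
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_max", "p_floor", "p_short", "artifact_rate", "seq_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.threshold_T >= self.L_ref:
            raise ValueError("require threshold_T < L_ref")
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        if self.genotype not in (PIF1, PIF1_M2):
            raise ValueError(f"unknown genotype {self.genotype!r}")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class CloneTruth:
    baseline_len: int
    extended: bool
    artifact: bool
    div_pos: int       # operational: first mismatch vs master, 1-based
    append_pos: int    # baseline_len + 1 where new sequence was appended
    n_units: int       # mutant blocks appended (0 if unextended)


@dataclass(frozen=True)
class SimClone:
    clone_id: str
    seq: str  # anchor + telomere (errors applied)
    truth: CloneTruth


@dataclass
class SimExperiment:
    config: SimConfig
    master: str  # clonal baseline tract; every baseline is a prefix
    clones: list[SimClone]

    def truth_table(self) -> pd.DataFrame:
        rows = [
            {
                "clone_id": c.clone_id,
                "baseline_len": c.truth.baseline_len,
                "extended": c.truth.extended,
                "artifact": c.truth.artifact,
                "div_pos": c.truth.div_pos,
                "append_pos": c.truth.append_pos,
                "n_units": c.truth.n_units,
            }
            for c in self.clones
        ]
        return pd.DataFrame(rows)


def extension_probability(L: int, cfg: SimConfig) -> float:
    """Per-cycle extension probability at telomere length ``L``.

    Non-increasing in L above the threshold; below it, PIF1 cells drop
    to ``p_short`` while pif1-m2 cells continue the trend at p(T).
    """
    if L < 0:
        raise ValueError("L must be >= 0")

    def trend(length: float) -> float:
        return cfg.p_floor + (cfg.p_max - cfg.p_floor) * max(
            0.0, 1.0 - length / cfg.L_ref
        )

    if L >= cfg.threshold_T:
        return trend(L)
    if cfg.genotype == PIF1_M2:
        return trend(cfg.threshold_T)
    return cfg.p_short


def _draw_baseline_len(cfg: SimConfig, rng: np.random.Generator) -> int:
    for _ in range(1000):
        x = rng.normal(cfg.baseline_mean, cfg.baseline_sd)
        if x >= cfg.baseline_min:
            return int(round(x))
    return cfg.baseline_min


def _mutant_extension(cfg: SimConfig, L: int, rng: np.random.Generator,
                      spec_tm: GrammarSpec) -> tuple[str, int]:
    mean_units = (
        cfg.mean_units_short if L < cfg.processivity_cutoff else cfg.mean_units_long
    )
    n_units = int(rng.geometric(1.0 / max(mean_units, 1.0)))
    blocks = [
        "TG" * int(rng.integers(0, spec_tm.tm_tg_max + 1)) + "TGG"
        for _ in range(n_units)
    ]
    return "".join(blocks) + "ATTTGG", n_units


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0 or not seq:
        return seq
    hits = rng.random(len(seq)) < rate
    if not hits.any():
        return seq
    out = list(seq)
    for i in np.flatnonzero(hits):
        alts = [b for b in "ACGT" if b != out[i]]
        out[i] = alts[int(rng.integers(0, 3))]
    return "".join(out)


def _first_mismatch(seq: str, master: str) -> int:
    """1-based first position where seq differs from master; len+1 if none."""
    for i, ch in enumerate(seq):
        if i >= len(master) or master[i] != ch:
            return i + 1
    return len(seq) + 1


def simulate_clone(
    cfg: SimConfig,
    rng: np.random.Generator,
    master: str,
    clone_id: str = "clone",
    spec_tel: GrammarSpec | None = None,
    spec_tm: GrammarSpec | None = None,
) -> SimClone:
    """Simulate one cloned telomere molecule against a given master tract."""
    spec_tel = spec_tel or tel_tract()
    spec_tm = spec_tm or tm_unit()
    L = min(_draw_baseline_len(cfg, rng), len(master))
    tel = master[:L]

    artifact = bool(rng.random() < cfg.artifact_rate) and L >= 2
    if artifact:
        keep = int(rng.integers(1, L))  # at least 1 bp kept and 1 replaced
        repl = generate_tract(spec_tel, L - keep, rng)[: L - keep]
        tel = tel[:keep] + repl

    p = extension_probability(len(tel), cfg)
    extended = bool(rng.random() < p)
    n_units = 0
    if extended:
        ext, n_units = _mutant_extension(cfg, len(tel), rng, spec_tm)
        tel = tel + ext

    div_pos = _first_mismatch(tel, master)
    truth = CloneTruth(
        baseline_len=L,
        extended=extended,
        artifact=artifact,
        div_pos=div_pos,
        append_pos=L + 1,
        n_units=n_units,
    )
    tel = _apply_errors(tel, cfg.seq_error_rate, rng)
    return SimClone(clone_id, cfg.anchor_seq + tel, truth)


def simulate_experiment(cfg: SimConfig) -> SimExperiment:
    """Simulate a full experiment of ``cfg.n_clones`` clones.

    Deterministic: identical config (including seed) gives identical
    output. The master tract is sampled once; baselines are its prefixes.
    """
    rng = np.random.default_rng(cfg.seed)
    # Master long enough to cover any plausible baseline draw.
    master_len = int(cfg.baseline_mean + 6 * cfg.baseline_sd) + 10
    master = generate_tract(tel_tract(), master_len, rng)
    tag = cfg.genotype.replace("-", "")
    clones = [
        simulate_clone(cfg, rng, master, f"{cfg.locus_id}_{tag}_c{i:04d}")
        for i in range(cfg.n_clones)
    ]
    return SimExperiment(cfg, master, clones)
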
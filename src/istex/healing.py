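"""Genetic telomere-addition (healing) assay calculations.

An HO-induced break carrying a telomeric seed either heals into a new
telomere — losing the distal LYS2 marker and conferring resistance to
alpha-aminoadipate (alpha-AA) — or is repaired/lost. Colonies are counted
before galactose induction, after induction, and after replica-plating
to alpha-AA.

Two frequency readouts are supported:

* standard: percent of post-galactose survivors that are alpha-AA
  resistant;
* alternative: resistant / (pre-galactose colonies - alpha-AA sensitive
  colonies), which shows the same threshold behavior with more
  variability between experiments.

Frequencies are routinely normalized to the pif1-m2 reference of the
same end, which cancels HO cutting efficiency and per-end telomerase
recruitment differences, leaving a clean readout of Pif1 activity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PlatingCount:
    strain_id: str
    genotype: str
    tg_len: int            # telomeric seed length in bp (e.g. 18, 34, 82)
    pre_gal: int
    post_gal: int
    resistant: int
    sensitive: int | None = None  # derived as post_gal - resistant if absent

    def __post_init__(self) -> None:
        if self.pre_gal <= 0:
            raise ValueError("pre_gal must be > 0")
        if not 0 <= self.resistant <= self.post_gal:
            raise ValueError("require 0 <= resistant <= post_gal")

    @property
    def n_sensitive(self) -> int:
        if self.sensitive is not None:
            return self.sensitive
        return self.post_gal - self.resistant


@dataclass(frozen=True)
class FrequencyResult:
    frequency_pct: float
    method: str  # "standard" | "alternative"


def addition_frequency(c: PlatingCount) -> float:
    """Percent of post-galactose survivors that are alpha-AA resistant."""
    if c.post_gal <= 0:
        raise ValueError("post_gal must be > 0 for the standard method")
    return 100.0 * c.resistant / c.post_gal


def addition_frequency_alt(c: PlatingCount) -> float:
    """Alternative readout: resistant / (pre-galactose - sensitive), as percent."""
    denom = c.pre_gal - c.n_sensitive
    if denom <= 0:
        raise ValueError("pre_gal - sensitive must be > 0 for the alternative method")
    return 100.0 * c.resistant / denom


def normalize_to_pif1(freq: float, freq_pif1m2: float) -> float:
    """Ratio of a frequency to its pif1-m2 reference (reference maps to 1)."""
    if freq_pif1m2 <= 0:
        raise ValueError("pif1-m2 reference frequency must be > 0")
    return freq / freq_pif1m2


def summarize_replicates(values: list[float]) -> tuple[float, float, int]:
    """Mean, sample (n-1) s.d. and n over replicate frequencies.

    With a single replicate the s.d. is undefined and returned as NaN.
    """
    if not values:
        raise ValueError("need at least one replicate")
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else math.nan
    return mean, sd, len(arr)
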
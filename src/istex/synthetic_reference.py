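"""Synthetic reconstruction of the published single-telomere window counts.

The published per-telomere source tables report, for each locus, how
many cloned telomeres below the transition threshold and within the
comparison window above it were extended:

* V-R (wild type): 2 of 32 telomeres shorter than 44 bp extended
  (6.3%), versus 65 of 136 between 44 and 86 bp (47.8%);
* VI-R (wild type): 2 of 13 below 38 bp (15.4%), versus 51 of 115
  between 38 and 74 bp (44.3%);

counted after excluding telomeres whose only divergence was wild type.

The per-clone records built here are SYNTHETIC stand-ins for those
deposited tables: undiverged lengths are spread deterministically over
each window and extension flags assigned to match the published
marginal counts exactly, plus a handful of wild-type-only (excluded)
records to exercise the exclusion rule. They carry the published
marginal information and nothing more — suitable for verifying the
window-table, exclusion, percentage and exact-test arithmetic, not for
re-deriving the thresholds themselves.
"""

from __future__ import annotations

import pandas as pd

PUBLISHED_WINDOWS = {
    # locus: (threshold, upper_hi, extended_below, n_below, extended_upper, n_upper)
    "V-R": (44, 86, 2, 32, 65, 136),
    "VI-R": (38, 74, 2, 13, 51, 115),
}


def _spread(lo: int, hi: int, n: int) -> list[int]:
    """n lengths spread evenly (deterministically) over [lo, hi]."""
    if n == 1:
        return [lo]
    span = hi - lo
    return [lo + (i * span) // (n - 1) for i in range(n)]


def synthetic_window_records(locus: str, n_excluded: int = 8) -> pd.DataFrame:
    """Synthetic per-clone call records matching the published margins."""
    thr, hi, k_below, n_below, k_upper, n_upper = PUBLISHED_WINDOWS[locus]
    rows = []

    def add(lengths, n_ext, group):
        for i, length in enumerate(lengths):
            rows.append(
                {
                    "clone_id": f"{locus}_{group}_{i:03d}",
                    "undiverged_len": length,
                    "extended": i < n_ext,
                    "excluded": False,
                }
            )

    add(_spread(max(5, thr - 30), thr - 1, n_below), k_below, "below")
    add(_spread(thr, hi, n_upper), k_upper, "upper")
    for i in range(n_excluded):  # wild-type-only divergence: excluded
        rows.append(
            {
                "clone_id": f"{locus}_wtonly_{i:03d}",
                "undiverged_len": thr + i,
                "extended": False,
                "excluded": True,
            }
        )
    return pd.DataFrame(rows)
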
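"""Strand-aware scanner for telomere-like (TG1-3)n tracts in arbitrary DNA.

Sequence this long outside telomeric regions is rare in the genome —
any tract above the healing threshold is a potential de novo telomere
seed — so the scanner reports every maximal interval whose sequence (or
reverse complement, reported on the minus strand) fully parses as a
generic telomeric tract.

"Correct orientation" is a strand filter left to the caller: at a
chromosome end the G-rich strand runs 5'->3' toward the end, so which
strand is "correct" depends on which side of the site the end would
form. The scanner itself is orientation-agnostic.

Coordinates here are 1-based inclusive on the forward strand; the
BED-like file output converts to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

from .grammar import GrammarSpec, tel_tract

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TractHit:
    seq_id: str
    start: int   # 1-based inclusive, forward strand
    end: int     # 1-based inclusive, forward strand
    strand: str  # "+" or "-"
    length: int
    tract_seq: str  # G-rich strand sequence (reverse-complemented for "-")


def _valid_run_ok(ch: str, run_len: int, spec: GrammarSpec) -> bool:
    if ch == "G":
        return run_len <= spec.g_max
    if ch == "T":
        return run_len <= spec.t_max
    return False


def _maximal_intervals(seq: str, min_len: int, spec: GrammarSpec):
    """Maximal valid (two-pointer) intervals of a run-bounded tract.

    Validity is hereditary (substrings of valid strings are valid), so a
    sliding window enumerates all maximal intervals in linear time.
    """
    n = len(seq)
    s = 0
    e = 0  # exclusive end of current valid window
    last_reported_end = -1
    while s < n:
        if e < s:
            e = s
        # extend e as far as the window [s, e) stays valid
        while e < n:
            ch = seq[e]
            if ch not in ("T", "G"):
                break
            run = 1
            j = e - 1
            while j >= s and seq[j] == ch:
                run += 1
                j -= 1
            if not _valid_run_ok(ch, run, spec):
                break
            e += 1
        if e - s >= min_len and e > last_reported_end:
            yield s, e
            last_reported_end = e
        if e == s:
            s += 1
            continue
        # advance s minimally so that e can grow; for run-bounded validity
        # the window is blocked by the run ending at e, so step s forward.
        s += 1


def scan_tracts(
    seq: str,
    min_len: int = 8,
    spec: GrammarSpec | None = None,
    seq_id: str = "seq",
    strands: str = "both",
) -> list[TractHit]:
    """All maximal telomere-like tracts of at least ``min_len`` bp.

    Forward-strand hits are runs of valid tract sequence; minus-strand
    hits are intervals whose reverse complement is valid (CA-type
    repeats on the forward strand). N and any other non-TG base breaks a
    tract. Hits are sorted by length descending, then coordinate.
    """
    if min_len < 8:
        raise ValueError("min_len must be >= 8")
    spec = spec or tel_tract()
    seq = seq.upper()
    for i, ch in enumerate(seq):
        if ch not in "ACGTN":
            raise ValueError(f"non-ACGTN character {ch!r} at position {i + 1}")
    hits: list[TractHit] = []
    if strands in ("both", "+"):
        for s, e in _maximal_intervals(seq, min_len, spec):
            hits.append(
                TractHit(seq_id, s + 1, e, "+", e - s, seq[s:e])
            )
    if strands in ("both", "-"):
        rc = revcomp(seq)
        n = len(seq)
        for s, e in _maximal_intervals(rc, min_len, spec):
            # rc positions s..e-1 map to forward n-e .. n-s-1
            fs, fe = n - e, n - s
            hits.append(
                TractHit(seq_id, fs + 1, fe, "-", e - s, rc[s:e])
            )
    hits.sort(key=lambda h: (-h.length, h.start, h.strand))
    return hits


def filter_hits(
    hits: list[TractHit],
    exclude: list[tuple[int, int]] | None = None,
    orientation: str = "both",
) -> list[TractHit]:
    """Drop hits on an unwanted strand or overlapping excluded intervals.

    Exclusions are 1-based closed intervals; a hit touching an excluded
    interval by even one base is removed (closed-interval overlap:
    hit.start <= ex.end and ex.start <= hit.end).
    """
    if orientation not in ("+", "-", "both"):
        raise ValueError("orientation must be '+', '-' or 'both'")
    exclude = exclude or []
    for lo, hi in exclude:
        if lo > hi:
            raise ValueError(f"malformed exclusion interval ({lo}, {hi})")
    out = []
    for h in hits:
        if orientation != "both" and h.strand != orientation:
            continue
        if any(h.start <= hi and lo <= h.end for lo, hi in exclude):
            continue
        out.append(h)
    return out
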
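"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive results by exhaustive search or exact
rational arithmetic, sharing no code with the implementation paths they
check.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb


# --- exhaustive tokenization -------------------------------------------------

def _unit_strings(grammar: str) -> list[str]:
    if grammar == "WT_UNIT":
        return [
            "TG" * a + "TGGGTGTG" + "G" * b
            for a in range(7)
            for b in range(2)
        ]
    if grammar == "TM_UNIT":
        return ["TG" * a + "TGG" for a in range(5)] + ["ATTTGG"]
    raise ValueError(grammar)


def brute_force_parsed_len(seq: str, grammar: str,
                           g_max: int = 3, t_max: int = 4) -> int:
    """Max prefix length coverable by any tokenization (exhaustive DFS)."""
    if grammar == "TEL_TRACT":
        # units are homopolymer runs; adjacent tokens must change letter
        best = 0

        def walk(pos: int, last: str) -> None:
            nonlocal best
            best = max(best, pos)
            for ch, bound in (("T", t_max), ("G", g_max)):
                if ch == last:
                    continue
                for run in range(1, bound + 1):
                    if seq[pos : pos + run] == ch * run:
                        walk(pos + run, ch)
                    else:
                        break

        walk(0, "")
        return best

    units = _unit_strings(grammar)
    best = 0
    seen: set[int] = set()

    def walk(pos: int) -> None:
        nonlocal best
        if pos in seen:
            return
        seen.add(pos)
        best = max(best, pos)
        for u in units:
            if seq.startswith(u, pos):
                walk(pos + len(u))

    walk(0)
    return best


# --- exact Fisher enumeration ------------------------------------------------

def enumeration_fisher_p(n11: int, n12: int, n21: int, n22: int) -> float:
    """Two-sided point-probability p by exact rational enumeration."""
    r1, r2 = n11 + n12, n21 + n22
    c1 = n11 + n21
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    denom = comb(n, c1)
    probs = {}
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs[x] = Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
    p_obs = probs[n11]
    total = sum(p for p in probs.values() if p <= p_obs)
    return float(total)


def all_point_probs(r1: int, r2: int, c1: int) -> list[Fraction]:
    n = r1 + r2
    denom = comb(n, c1)
    return [
        Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
    ]


def enumerate_tga_strings(max_len: int):
    """Every string over {T, G, A} up to max_len (including empty)."""
    for length in range(max_len + 1):
        for tup in itertools.product("TGA", repeat=length):
            yield "".join(tup)
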
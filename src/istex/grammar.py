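"""Repeat grammars for budding-yeast telomeric DNA.

Three grammars are defined, all on the G-rich strand read 5'→3':

* ``TEL_TRACT`` — the generic heterogeneous telomeric tract, (TG1-3)n.
  Modelled as any string over {T, G} whose maximal G-runs are at most
  ``g_max`` (default 3) and whose maximal T-runs are at most ``t_max``
  (default 4; strict (TG1-3)n would forbid TT, but natural tracts carry
  short T-runs and a permissive bound avoids false divergence calls).
* ``WT_UNIT`` — the repeat unit added by wild-type telomerase:
  5'-(TG)a TGGGTGTG (G)b-3' with a in 0..6 and b in 0..1.
* ``TM_UNIT`` — the repeat unit added by the tlc1-tm template-mutant
  telomerase: blocks 5'-(TG)a TGG-3' with a in 0..4, closed by the
  terminator 5'-ATTTGG-3'.

Two hard diagnostics separate mutant from wild-type sequence: the base A
occurs in telomeric G-strand DNA only inside the mutant terminator, and
G-runs of three occur only in wild-type repeats (mutant blocks never
exceed GG, including across block/terminator junctions).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from enum import Enum


class GrammarId(str, Enum):
    TEL_TRACT = "TEL_TRACT"
    WT_UNIT = "WT_UNIT"
    TM_UNIT = "TM_UNIT"


class SegmentClass(str, Enum):
    MUTANT = "MUTANT"
    WILDTYPE = "WILDTYPE"
    MIXED = "MIXED"
    AMBIGUOUS = "AMBIGUOUS"
    NONE = "NONE"


TM_TERMINATOR = "ATTTGG"
WT_CORE = "TGGGTGTG"

_VALID_BASES = frozenset("ACGT")


class SequenceError(ValueError):
    """Raised for malformed DNA input (non-ACGT characters)."""


@dataclass(frozen=True)
class GrammarSpec:
    """Parameter bundle for one of the three repeat grammars.

    Only the bounds relevant to ``id`` are consulted.
    """

    id: GrammarId
    g_max: int = 3          # TEL_TRACT: max G-run
    t_max: int = 4          # TEL_TRACT: max T-run
    wt_tg_max: int = 6      # WT_UNIT: (TG)a with a in 0..wt_tg_max
    wt_g_tail_max: int = 1  # WT_UNIT: trailing (G)b with b in 0..wt_g_tail_max
    tm_tg_max: int = 4      # TM_UNIT: blocks (TG)a TGG with a in 0..tm_tg_max

    def __post_init__(self) -> None:
        if self.g_max < 1:
            raise ValueError("g_max must be >= 1")
        for name in ("t_max", "wt_tg_max", "wt_g_tail_max", "tm_tg_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def tel_tract(g_max: int = 3, t_max: int = 4) -> GrammarSpec:
    return GrammarSpec(GrammarId.TEL_TRACT, g_max=g_max, t_max=t_max)


def wt_unit(tg_max: int = 6, g_tail_max: int = 1) -> GrammarSpec:
    return GrammarSpec(GrammarId.WT_UNIT, wt_tg_max=tg_max, wt_g_tail_max=g_tail_max)


def tm_unit(tg_max: int = 4) -> GrammarSpec:
    return GrammarSpec(GrammarId.TM_UNIT, tm_tg_max=tg_max)


@dataclass(frozen=True)
class RepeatToken:
    text: str
    grammar_id: GrammarId
    start: int  # 1-based inclusive, within the parsed segment
    end: int    # 1-based inclusive


@dataclass
class TokenizationResult:
    tokens: list[RepeatToken]
    fully_parsed: bool
    parsed_len: int


def _check_dna(seq: str) -> str:
    seq = seq.upper()
    for i, ch in enumerate(seq):
        if ch not in _VALID_BASES:
            raise SequenceError(f"non-ACGT character {ch!r} at position {i + 1}")
    return seq


@functools.lru_cache(maxsize=None)
def unit_inventory(spec: GrammarSpec) -> tuple[str, ...]:
    """All unit strings of a unit-based grammar, longest first.

    For TM_UNIT the inventory contains the blocks and the terminator; units
    may be concatenated freely (a tokenized segment need not end in a
    terminator — clones are cut off wherever sequencing stopped).
    """
    if spec.id is GrammarId.WT_UNIT:
        units = [
            "TG" * a + WT_CORE + "G" * b
            for a in range(spec.wt_tg_max + 1)
            for b in range(spec.wt_g_tail_max + 1)
        ]
    elif spec.id is GrammarId.TM_UNIT:
        units = ["TG" * a + "TGG" for a in range(spec.tm_tg_max + 1)]
        units.append(TM_TERMINATOR)
    else:
        raise ValueError("TEL_TRACT is run-bounded, not unit-based")
    return tuple(sorted(set(units), key=len, reverse=True))


def _tel_tract_prefix_len(seq: str, spec: GrammarSpec) -> int:
    """Length of the longest prefix that is a valid (TG1-3)n-style tract."""
    run_char = ""
    run_len = 0
    for i, ch in enumerate(seq):
        if ch not in ("T", "G"):
            return i
        if ch == run_char:
            run_len += 1
        else:
            run_char, run_len = ch, 1
        bound = spec.g_max if ch == "G" else spec.t_max
        if run_len > bound:
            return i
    return len(seq)


def _tel_tract_tokens(prefix: str) -> list[RepeatToken]:
    """Tokenize a valid tract into its maximal homopolymer runs."""
    tokens: list[RepeatToken] = []
    i = 0
    while i < len(prefix):
        j = i
        while j < len(prefix) and prefix[j] == prefix[i]:
            j += 1
        tokens.append(RepeatToken(prefix[i:j], GrammarId.TEL_TRACT, i + 1, j))
        i = j
    return tokens


def parses_fully(seq: str, spec: GrammarSpec) -> bool:
    """True iff the whole of ``seq`` parses under ``spec``."""
    return tokenize(seq, spec).fully_parsed


def tokenize(seq: str, spec: GrammarSpec) -> TokenizationResult:
    """Tokenize the maximal parsable prefix of ``seq`` under ``spec``.

    Parsing is complete-prefix-optimal: ``parsed_len`` is the largest
    number of prefix base pairs coverable by any concatenation of units
    (dynamic programming over unit lengths). Among tokenizations covering
    that prefix, longer units are preferred greedily from the 5' end.
    """
    seq = _check_dna(seq)
    n = len(seq)
    if spec.id is GrammarId.TEL_TRACT:
        plen = _tel_tract_prefix_len(seq, spec)
        return TokenizationResult(_tel_tract_tokens(seq[:plen]), plen == n, plen)

    units = unit_inventory(spec)
    reachable = [False] * (n + 1)
    reachable[0] = True
    for i in range(n):
        if not reachable[i]:
            continue
        for u in units:
            if seq.startswith(u, i):
                reachable[i + len(u)] = True
    plen = max(i for i in range(n + 1) if reachable[i])

    # ok[i]: from position i, the remainder up to plen is unit-coverable.
    ok = [False] * (plen + 1)
    ok[plen] = True
    for i in range(plen - 1, -1, -1):
        ok[i] = any(
            seq.startswith(u, i) and i + len(u) <= plen and ok[i + len(u)]
            for u in units
        )
    tokens: list[RepeatToken] = []
    i = 0
    while i < plen:
        for u in units:  # longest first: ties broken longest-unit-first
            if seq.startswith(u, i) and i + len(u) <= plen and ok[i + len(u)]:
                tokens.append(RepeatToken(u, spec.id, i + 1, i + len(u)))
                i += len(u)
                break
        else:  # pragma: no cover - DP guarantees progress
            raise AssertionError("tokenization reconstruction failed")
    return TokenizationResult(tokens, plen == n, plen)


def _weights(k: int, decay: float) -> list[float]:
    w = [decay**i for i in range(k)]
    s = sum(w)
    return [x / s for x in w]


def generate_tract(spec: GrammarSpec, target_len: int, rng) -> str:
    """Sample a tract of roughly ``target_len`` bp that fully parses.

    The returned string is at least ``target_len`` long and overshoots by
    less than one unit (run). Deterministic for a given numpy Generator
    state. TM_UNIT tracts always close with the ATTTGG terminator, as the
    mutant template does.
    """
    if target_len < 0:
        raise ValueError("target_len must be >= 0")
    if target_len == 0:
        return ""
    parts: list[str] = []
    total = 0
    if spec.id is GrammarId.TEL_TRACT:
        # Alternate T-runs and G-runs; short runs dominate, as in natural
        # (TG1-3)n sequence.
        t_w = _weights(spec.t_max, 0.25)
        g_w = _weights(spec.g_max, 0.6)
        emit_t = True
        while total < target_len:
            if emit_t:
                run = "T" * (1 + int(rng.choice(spec.t_max, p=t_w)))
            else:
                run = "G" * (1 + int(rng.choice(spec.g_max, p=g_w)))
            parts.append(run)
            total += len(run)
            emit_t = not emit_t
    elif spec.id is GrammarId.WT_UNIT:
        while total < target_len:
            a = int(rng.integers(0, spec.wt_tg_max + 1))
            b = int(rng.integers(0, spec.wt_g_tail_max + 1))
            u = "TG" * a + WT_CORE + "G" * b
            parts.append(u)
            total += len(u)
    elif spec.id is GrammarId.TM_UNIT:
        while total < max(0, target_len - len(TM_TERMINATOR)):
            u = "TG" * int(rng.integers(0, spec.tm_tg_max + 1)) + "TGG"
            parts.append(u)
            total += len(u)
        parts.append(TM_TERMINATOR)
    else:  # pragma: no cover
        raise ValueError(f"unknown grammar {spec.id}")
    return "".join(parts)


def has_g_run(seq: str, length: int = 3) -> bool:
    return "G" * length in seq


def partial_terminator_at_end(seq: str) -> int | None:
    """0-based start of a truncated ATTTGG prefix at the 3' end, if any.

    Only prefixes that include the diagnostic A qualify ("A", "AT", ...,
    "ATTTG"); a clone whose sequencing stopped mid-terminator still shows
    the A that wild-type G-strand DNA never contains.
    """
    for k in range(len(TM_TERMINATOR) - 1, 0, -1):
        if seq.endswith(TM_TERMINATOR[:k]):
            return len(seq) - k
    return None


def classify_segment(
    seq: str,
    min_call_len: int = 6,
    spec_tel: GrammarSpec | None = None,
    spec_tm: GrammarSpec | None = None,
    require_full_terminator: bool = False,
    tm_block_parse_calls_mutant: bool = False,
) -> SegmentClass:
    """Classify a divergent segment as mutant, wild type, mixed or ambiguous.

    Mutant evidence: an ATTTGG terminator anywhere, or (unless
    ``require_full_terminator``) a truncated terminator carrying an A at
    the 3' end. Wild-type evidence: a G-run of three or more, which the
    mutant template never produces. Both kinds of evidence present =>
    MIXED. A-free, GGG-free segments of at least ``min_call_len`` that
    parse only as a generic tract are WILDTYPE; segments compatible with
    both grammars are AMBIGUOUS by default (``tm_block_parse_calls_mutant``
    makes mutant-block-parsable ones MUTANT instead). Shorter segments and
    anything else are AMBIGUOUS; the empty segment is NONE.
    """
    if min_call_len < 1:
        raise ValueError("min_call_len must be >= 1")
    seq = _check_dna(seq)
    if not seq:
        return SegmentClass.NONE
    spec_tel = spec_tel or tel_tract()
    spec_tm = spec_tm or tm_unit()

    mutant_ev = TM_TERMINATOR in seq
    if not mutant_ev and not require_full_terminator:
        mutant_ev = partial_terminator_at_end(seq) is not None
    wt_ev = has_g_run(seq, spec_tel.g_max)

    if mutant_ev and wt_ev:
        return SegmentClass.MIXED
    if mutant_ev:
        return SegmentClass.MUTANT
    if "A" in seq:  # A outside any terminator context: unclassifiable
        return SegmentClass.AMBIGUOUS
    if len(seq) < min_call_len:
        return SegmentClass.AMBIGUOUS
    tel_ok = parses_fully(seq, spec_tel)
    if wt_ev:
        return SegmentClass.WILDTYPE if tel_ok else SegmentClass.AMBIGUOUS
    # No hard diagnostic: long enough, A-free, GGG-free.
    blocks_ok = _parses_as_tm_blocks(seq, spec_tm)
    if blocks_ok:
        return (
            SegmentClass.MUTANT
            if tm_block_parse_calls_mutant
            else SegmentClass.AMBIGUOUS
        )
    if tel_ok:
        return SegmentClass.WILDTYPE
    return SegmentClass.AMBIGUOUS


def _parses_as_tm_blocks(seq: str, spec_tm: GrammarSpec) -> bool:
    """True iff ``seq`` is a concatenation of (TG)a TGG blocks only."""
    blocks = tuple(
        u for u in unit_inventory(spec_tm) if u != TM_TERMINATOR
    )
    n = len(seq)
    reachable = [False] * (n + 1)
    reachable[0] = True
    for i in range(n):
        if reachable[i]:
            for b in blocks:
                if seq.startswith(b, i):
                    reachable[i + len(b)] = True
    return reachable[n]


def tm_block_suffix_start(seq: str, end: int, spec_tm: GrammarSpec | None = None) -> int:
    """Smallest 0-based j such that seq[j:end] is a concatenation of TM blocks.

    Used to pull the mutant blocks preceding a terminator into the mutant
    segment. Returns ``end`` when no block ends exactly at ``end``.
    """
    spec_tm = spec_tm or tm_unit()
    blocks = tuple(u for u in unit_inventory(spec_tm) if u != TM_TERMINATOR)
    ok = [False] * (end + 1)
    ok[end] = True
    best = end
    for j in range(end - 1, -1, -1):
        ok[j] = any(
            seq.startswith(b, j) and j + len(b) <= end and ok[j + len(b)]
            for b in blocks
        )
        if ok[j]:
            best = j
    return best
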
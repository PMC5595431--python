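"""Sequence-divergence calling on cloned telomeres.

Each sequenced clone shares its proximal sequence with the clonal
baseline population; new sequence (telomerase extension, recombination,
or amplification/cloning artifact) stops aligning at the divergence
point. Calling proceeds per locus:

1. trim the subtelomeric anchor (clones without an acceptable anchor
   match are rejected, not fatal);
2. build a positional-majority consensus in two passes, the second pass
   using only each clone's pre-divergence prefix (or use a known
   reference);
3. locate the divergence point with a windowed-mismatch rule that
   tolerates isolated sequencing/PCR errors;
4. split the divergent suffix into a wild-type (grey) part and a mutant
   (red) part anchored at the first terminator evidence, and classify.

Comparisons are strictly positional (no gapped alignment): an early
indel manifests as divergence, matching the "no longer aligns" reading.
Coordinates are 1-based and inclusive; position 1 is the first base
after the anchor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .grammar import (
    GrammarSpec,
    SegmentClass,
    SequenceError,
    TM_TERMINATOR,
    _check_dna,
    classify_segment,
    partial_terminator_at_end,
    tm_block_suffix_start,
)

PIF1 = "PIF1"
PIF1_M2 = "pif1-m2"


class AnchorNotFoundError(ValueError):
    """No acceptable anchor match in a clone sequence."""


@dataclass(frozen=True)
class TelomereClone:
    clone_id: str
    locus_id: str
    genotype: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("clone sequence must be non-empty")


@dataclass(frozen=True)
class AnchorSpec:
    locus_id: str
    anchor_seq: str
    max_anchor_mismatch: int = 2

    def __post_init__(self) -> None:
        if len(self.anchor_seq) < 12:
            raise ValueError("anchor_seq must be at least 12 bp")


@dataclass(frozen=True)
class DivergenceParams:
    """Windowed-mismatch divergence rule parameters.

    A divergence is called at the first mismatch whose following
    ``window_w`` bp window holds at least ``window_k`` mismatches against
    the reference; sparser mismatches are treated as sequencing/PCR
    error. With error-free data ``window_k=1`` pinpoints the first
    mismatch exactly.

    Defaults (w=12, k=3) are tuned to TG-repeat sequence: mutant and
    wild-type tracts are both near-periodic TG, so positional identity
    beyond a true divergence point is ~50% and a short dense window
    fires several bases late; a wider, sparser window anchors the call
    at the first truly divergent base while still ignoring isolated
    errors (three mismatches within 12 bp from sequencing error alone is
    vanishingly rare at per-base error rates below 1%).
    """

    window_w: int = 12
    window_k: int = 3
    min_call_len: int = 6
    max_anchor_mismatch: int = 2

    def __post_init__(self) -> None:
        if not (1 <= self.window_k <= self.window_w):
            raise ValueError("require 1 <= window_k <= window_w")


@dataclass
class ConsensusProfile:
    bases: str
    depth: list[int]

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class DivergenceCall:
    clone_id: str
    locus_id: str
    genotype: str
    total_len: int
    undiverged_len: int
    wt_div_len: int
    mutant_div_len: int
    div_class: SegmentClass
    extended: bool
    excluded: bool


def trim_anchor(clone: TelomereClone, anchor: AnchorSpec) -> str:
    """Telomere-only suffix following the anchor match.

    The anchor is slid from the 5' end; the first offset with at most
    ``max_anchor_mismatch`` substitutions wins.
    """
    if clone.locus_id != anchor.locus_id:
        raise ValueError(
            f"clone locus {clone.locus_id!r} != anchor locus {anchor.locus_id!r}"
        )
    seq = _check_dna(clone.seq)
    a = _check_dna(anchor.anchor_seq)
    la = len(a)
    for off in range(len(seq) - la + 1):
        mism = 0
        for i in range(la):
            if seq[off + i] != a[i]:
                mism += 1
                if mism > anchor.max_anchor_mismatch:
                    break
        else:
            return seq[off + la :]
    raise AnchorNotFoundError(
        f"clone {clone.clone_id}: no anchor match with <= "
        f"{anchor.max_anchor_mismatch} mismatches"
    )


def _majority(
    seqs: list[str],
) -> tuple[str, list[int]]:
    """Per-position majority base and depth over ragged sequences.

    Ties go to the base carried by the longest contributing sequence,
    then alphabetically.
    """
    if not seqs:
        return "", []
    max_len = max(len(s) for s in seqs)
    bases: list[str] = []
    depth: list[int] = []
    for i in range(max_len):
        counts: dict[str, int] = {}
        for s in seqs:
            if i < len(s):
                counts[s[i]] = counts.get(s[i], 0) + 1
        top = max(counts.values())
        tied = sorted(b for b, c in counts.items() if c == top)
        if len(tied) > 1:
            # longest contributing sequence wins, then alphabetical
            best_len = -1
            pick = tied[0]
            for b in tied:
                lb = max(len(s) for s in seqs if i < len(s) and s[i] == b)
                if lb > best_len:
                    best_len, pick = lb, b
            tied = [pick]
        bases.append(tied[0])
        depth.append(sum(counts.values()))
    return "".join(bases), depth


def build_consensus(
    tel_seqs: list[str], params: DivergenceParams | None = None
) -> ConsensusProfile:
    """Two-pass positional-majority consensus of telomere-only sequences.

    Pass 1 takes the majority over all sequences; pass 2 calls a
    provisional divergence for every clone against the pass-1 consensus
    and rebuilds the majority from pre-divergence prefixes only, so that
    newly added (divergent) sequence does not pollute the distal
    consensus. Deterministic.
    """
    if len(tel_seqs) < 2:
        raise ValueError("need >= 2 sequences (use reference mode otherwise)")
    params = params or DivergenceParams()
    tel_seqs = [_check_dna(s) for s in tel_seqs]
    pass1_bases, _ = _majority(tel_seqs)
    prefixes = []
    for s in tel_seqs:
        d = find_divergence(s, pass1_bases, params)
        prefixes.append(s[: d - 1])
    prefixes = [p for p in prefixes if p]
    if not prefixes:
        prefixes = tel_seqs
    bases, depth = _majority(prefixes)
    return ConsensusProfile(bases, depth)


def find_divergence(
    tel_seq: str,
    ref: ConsensusProfile | str,
    params: DivergenceParams | None = None,
) -> int:
    """1-based divergence position, or ``len(tel_seq) + 1`` if none.

    Positions beyond the reference count as mismatches (sequence added
    past the consensus end is divergent); positions beyond the clone end
    simply truncate the window. A clone that is a clean prefix of the
    reference has eroded, not diverged.
    """
    if not tel_seq:
        raise ValueError("tel_seq must be non-empty")
    params = params or DivergenceParams()
    ref_str = ref.bases if isinstance(ref, ConsensusProfile) else ref
    tel_seq = _check_dna(tel_seq)
    n, m = len(tel_seq), len(ref_str)
    mism = [i >= m or tel_seq[i] != ref_str[i] for i in range(n)]
    w, k = params.window_w, params.window_k
    for i in range(n):
        if mism[i] and sum(mism[i : i + w]) >= k:
            return i + 1
    return n + 1


def call_clone(
    clone: TelomereClone,
    consensus: ConsensusProfile | str,
    params: DivergenceParams | None = None,
    spec_tm: GrammarSpec | None = None,
    **classify_kwargs,
) -> DivergenceCall:
    """Full divergence call for one anchor-trimmed clone.

    The divergent suffix is split at the first terminator evidence
    (ATTTGG, or a truncated terminator at the clone's 3' end), pulled
    backward through any contiguous run of mutant (TG)a TGG blocks: that
    part is mutant (red); whatever precedes it within the divergent
    suffix is wild-type divergence (grey). A suffix with no terminator
    evidence is classified as a whole; an AMBIGUOUS suffix is treated as
    no event but recorded.
    """
    params = params or DivergenceParams()
    tel = _check_dna(clone.seq)
    d = find_divergence(tel, consensus, params)
    suffix = tel[d - 1 :]
    base = dict(
        clone_id=clone.clone_id,
        locus_id=clone.locus_id,
        genotype=clone.genotype,
        total_len=len(tel),
        undiverged_len=d - 1,
    )
    if not suffix:
        return DivergenceCall(
            **base, wt_div_len=0, mutant_div_len=0,
            div_class=SegmentClass.NONE, extended=False, excluded=False,
        )
    t = suffix.find(TM_TERMINATOR)
    if t < 0:
        t_partial = partial_terminator_at_end(suffix)
        t = t_partial if t_partial is not None else -1
    if t >= 0:
        j = tm_block_suffix_start(suffix, t, spec_tm)
        wt_len, mut_len = j, len(suffix) - j
        cls = SegmentClass.MIXED if wt_len > 0 else SegmentClass.MUTANT
        return DivergenceCall(
            **base, wt_div_len=wt_len, mutant_div_len=mut_len,
            div_class=cls, extended=True, excluded=False,
        )
    cls = classify_segment(suffix, params.min_call_len, **classify_kwargs)
    if cls is SegmentClass.WILDTYPE:
        return DivergenceCall(
            **base, wt_div_len=len(suffix), mutant_div_len=0,
            div_class=cls, extended=False, excluded=True,
        )
    # AMBIGUOUS (short or unclassifiable) tail: recorded, no event.
    return DivergenceCall(
        **base, wt_div_len=0, mutant_div_len=0,
        div_class=cls, extended=False, excluded=False,
    )


CALL_COLUMNS = [
    "clone_id", "locus", "genotype", "total_len", "undiverged_len",
    "wt_div_len", "mutant_div_len", "class", "extended", "excluded",
]


def calls_to_table(calls: list[DivergenceCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "clone_id": c.clone_id,
                "locus": c.locus_id,
                "genotype": c.genotype,
                "total_len": c.total_len,
                "undiverged_len": c.undiverged_len,
                "wt_div_len": c.wt_div_len,
                "mutant_div_len": c.mutant_div_len,
                "class": c.div_class.value,
                "extended": c.extended,
                "excluded": c.excluded,
            }
            for c in calls
        ],
        columns=CALL_COLUMNS,
    )


def process_experiment(
    clones: list[TelomereClone],
    anchors: dict[str, AnchorSpec] | AnchorSpec,
    params: DivergenceParams | None = None,
    mode: str = "consensus",
    reference: str | None = None,
    **classify_kwargs,
) -> tuple[pd.DataFrame, list[str]]:
    """Run trim → consensus/reference → call over one locus.

    Returns the per-clone call table and a rejection log (clones with no
    anchor match or malformed sequence). Raises on an empty or
    mixed-locus clone list, or when no clone survives trimming.
    """
    if not clones:
        raise ValueError("empty clone list")
    loci = {c.locus_id for c in clones}
    if len(loci) > 1:
        raise ValueError(f"clones span multiple loci: {sorted(loci)}")
    locus = loci.pop()
    anchor = anchors[locus] if isinstance(anchors, dict) else anchors
    params = params or DivergenceParams()
    if params.max_anchor_mismatch != anchor.max_anchor_mismatch:
        anchor = AnchorSpec(anchor.locus_id, anchor.anchor_seq,
                            params.max_anchor_mismatch)

    rejections: list[str] = []
    trimmed: list[tuple[TelomereClone, str]] = []
    for c in clones:
        try:
            tel = trim_anchor(c, anchor)
            if not tel:
                raise AnchorNotFoundError(f"clone {c.clone_id}: empty telomere")
            trimmed.append((c, tel))
        except (AnchorNotFoundError, SequenceError) as exc:
            rejections.append(str(exc))
    if not trimmed:
        raise RuntimeError("zero accepted clones")

    if mode == "consensus":
        if len(trimmed) < 2:
            raise ValueError("consensus mode needs >= 2 accepted clones")
        ref: ConsensusProfile | str = build_consensus(
            [t for _, t in trimmed], params
        )
    elif mode == "reference":
        if not reference:
            raise ValueError("reference mode requires a reference sequence")
        ref = _check_dna(reference)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    calls = [
        call_clone(
            TelomereClone(c.clone_id, c.locus_id, c.genotype, tel),
            ref, params, **classify_kwargs,
        )
        for c, tel in trimmed
    ]
    return calls_to_table(calls), rejections
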
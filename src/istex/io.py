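"""Shared file I/O: FASTA (via Biopython), TSV tables, run configs.

Conventions: TSV (never CSV) with a header row, UTF-8; FASTA written
with 60-column wrapping; clone metadata is carried in FASTA headers as
``key=value`` tokens (locus=..., genotype=...). Coordinates are 1-based
closed in report tables and 0-based half-open only in BED-like output.
"""

from __future__ import annotations

import io as _io
import json
import os
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .divergence import AnchorSpec, TelomereClone
from .healing import PlatingCount
from .simulate import SimExperiment
from .tracts import TractHit


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read FASTA records (case-insensitive sequence, CRLF tolerated)."""
    with open(path, newline=None) as fh:
        return list(SeqIO.parse(fh, "fasta"))


def write_fasta(records: list[SeqRecord], path: str | Path) -> None:
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    os.replace(tmp, path)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, sep="\t", index=False)
    os.replace(tmp, path)


def _header_attrs(description: str) -> dict[str, str]:
    return dict(
        tok.split("=", 1) for tok in description.split() if "=" in tok
    )


def clones_from_fasta(path: str | Path, locus: str | None = None,
                      genotype: str | None = None) -> list[TelomereClone]:
    """Parse clone records; locus/genotype come from header attributes
    (``locus=V-R genotype=PIF1``) unless overridden."""
    clones = []
    for rec in read_fasta(path):
        attrs = _header_attrs(rec.description)
        clones.append(
            TelomereClone(
                clone_id=rec.id,
                locus_id=locus or attrs.get("locus", "unknown"),
                genotype=genotype or attrs.get("genotype", "unknown"),
                seq=str(rec.seq).upper(),
            )
        )
    return clones


def anchors_from_fasta(path: str | Path,
                       max_anchor_mismatch: int = 2) -> dict[str, AnchorSpec]:
    """Anchor records keyed by locus: the record id is the locus id."""
    return {
        rec.id: AnchorSpec(rec.id, str(rec.seq).upper(), max_anchor_mismatch)
        for rec in read_fasta(path)
    }


def experiment_to_records(exp: SimExperiment) -> list[SeqRecord]:
    return [
        SeqRecord(
            Seq(c.seq),
            id=c.clone_id,
            description=(
                f"locus={exp.config.locus_id} genotype={exp.config.genotype} "
                f"seed={exp.config.seed}"
            ),
        )
        for c in exp.clones
    ]


def write_experiment(exp: SimExperiment, outdir: str | Path,
                     prefix: str = "istex") -> dict[str, Path]:
    """Write FASTA + truth TSV + resolved config JSON for one experiment."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / f"{prefix}_clones.fasta",
        "truth": outdir / f"{prefix}_truth.tsv",
        "config": outdir / f"{prefix}_config.json",
    }
    write_fasta(experiment_to_records(exp), paths["fasta"])
    write_table(exp.truth_table(), paths["truth"])
    tmp = paths["config"].with_suffix(".json.tmp")
    tmp.write_text(exp.config.to_json() + "\n")
    os.replace(tmp, paths["config"])
    return paths


def plating_counts_from_table(df: pd.DataFrame) -> list[PlatingCount]:
    counts = []
    for row in df.itertuples(index=False):
        sens = getattr(row, "sensitive", None)
        counts.append(
            PlatingCount(
                strain_id=str(row.strain_id),
                genotype=str(row.genotype),
                tg_len=int(row.tg_len),
                pre_gal=int(row.pre_gal),
                post_gal=int(row.post_gal),
                resistant=int(row.resistant),
                sensitive=None if sens is None or pd.isna(sens) else int(sens),
            )
        )
    return counts


def hits_to_bed_table(hits: list[TractHit]) -> pd.DataFrame:
    """BED-like table: 0-based half-open start/end on the forward strand."""
    return pd.DataFrame(
        [
            {
                "seq_id": h.seq_id,
                "start": h.start - 1,
                "end": h.end,
                "name": f"tract_{h.length}bp",
                "length": h.length,
                "strand": h.strand,
                "tract_seq": h.tract_seq,
            }
            for h in hits
        ],
        columns=["seq_id", "start", "end", "name", "length", "strand", "tract_seq"],
    )


def write_json(obj, path: str | Path) -> None:
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    os.replace(tmp, path)
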
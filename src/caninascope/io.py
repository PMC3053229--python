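"""File formats: FASTA alignments, BED-like coding masks, observation and
assay tables (TSV).  All coordinates are 0-based half-open alignment
columns; tables are TSV with '.' for missing values."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .allele_calling import CloneAlignment
from .pyroseq_sim import OBSERVATION_COLUMNS, SNPAssay

__all__ = [
    "read_fasta_alignment",
    "write_fasta_alignment",
    "read_coding_mask",
    "write_coding_mask",
    "read_frequency_table",
    "write_frequency_table",
    "read_assay_table",
    "write_assay_table",
]

MISSING = "."


def read_fasta_alignment(
    path, locus: str | None = None, coding_mask=None
) -> CloneAlignment:
    """Read an aligned multi-FASTA of clones.

    Headers follow the ``>cloneID|individual`` dialect; a header without a
    ``|`` yields an empty individual.  Sequences are uppercased; ragged
    lengths, empty files and non-IUPAC characters are rejected.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty or not FASTA")
    names, individuals, seqs = [], [], []
    for rec in records:
        clone, _, individual = rec.id.partition("|")
        names.append(clone)
        individuals.append(individual)
        seqs.append(str(rec.seq))
    return CloneAlignment(
        locus=locus or path.stem,
        names=names,
        sequences=seqs,
        individuals=individuals,
        coding_mask=list(coding_mask) if coding_mask else [],
    )


def write_fasta_alignment(path, names, sequences, individuals=None) -> None:
    individuals = individuals or [""] * len(names)
    records = [
        SeqRecord(Seq(seq), id=f"{name}|{ind}" if ind else name, description="")
        for name, ind, seq in zip(names, individuals, sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_coding_mask(path) -> list[tuple[int, int]]:
    """BED-style 3-column intervals (name, start, end), 0-based half-open,
    relative to alignment columns."""
    intervals = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns")
        start, end = int(parts[1]), int(parts[2])
        if not 0 <= start < end:
            raise ValueError(f"{path}:{lineno}: bad interval [{start}, {end})")
        intervals.append((start, end))
    return sorted(intervals)


def write_coding_mask(path, name: str, intervals) -> None:
    lines = [f"{name}\t{s}\t{e}" for s, e in intervals]
    Path(path).write_text("\n".join(lines) + "\n")


def read_frequency_table(path) -> pd.DataFrame:
    """Read and validate a FrequencyObservation TSV.

    Columns: assay_id, locus, template, individual, bud_stage, replicate,
    fraction, depth.  gDNA rows are forced to bud_stage 'NA'; fractions are
    range-checked and duplicate measurement keys rejected, each with the
    offending 1-based row number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[MISSING], keep_default_na=False)
    missing_cols = set(OBSERVATION_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing columns {sorted(missing_cols)}")
    df = df[OBSERVATION_COLUMNS].copy()
    df["replicate"] = df["replicate"].astype(int)
    df["fraction"] = df["fraction"].astype(float)
    df["depth"] = pd.to_numeric(df["depth"], errors="coerce")
    bad_template = df[~df["template"].isin(["gDNA", "cDNA"])]
    if len(bad_template):
        row = bad_template.index[0] + 2  # header + 1-based
        raise ValueError(f"{path}: row {row}: unknown template {bad_template.iloc[0]['template']!r}")
    bad_frac = df[(df["fraction"] < 0) | (df["fraction"] > 1)]
    if len(bad_frac):
        row = bad_frac.index[0] + 2
        raise ValueError(f"{path}: row {row}: fraction {bad_frac.iloc[0]['fraction']} outside [0, 1]")
    df.loc[df["template"] == "gDNA", "bud_stage"] = "NA"
    key = ["assay_id", "template", "individual", "bud_stage", "replicate"]
    dup = df.duplicated(subset=key)
    if dup.any():
        row = int(np.flatnonzero(dup)[0]) + 2
        raise ValueError(f"{path}: row {row}: duplicated measurement key")
    return df


def write_frequency_table(df: pd.DataFrame, path) -> None:
    out = df[OBSERVATION_COLUMNS].copy()
    out.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def read_assay_table(path) -> list[SNPAssay]:
    """SNPAssay TSV: assay_id, locus, position, diagnostic_base,
    carrier_alleles (comma-separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"assay_id", "locus", "position", "diagnostic_base", "carrier_alleles"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        SNPAssay(
            assay_id=row.assay_id,
            locus=row.locus,
            position=int(row.position),
            diagnostic_base=row.diagnostic_base,
            carrier_alleles=frozenset(row.carrier_alleles.split(",")),
        )
        for row in df.itertuples()
    ]


def write_assay_table(assays: list[SNPAssay], path) -> None:
    df = pd.DataFrame(
        [
            {
                "assay_id": a.assay_id,
                "locus": a.locus,
                "position": a.position,
                "diagnostic_base": a.diagnostic_base,
                "carrier_alleles": ",".join(sorted(a.carrier_alleles)),
            }
            for a in assays
        ]
    )
    df.to_csv(path, sep="\t", index=False)
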
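"""Substitution counting and NG86 dN/dS on in-frame codon alignments."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._codons import (
    SENSE_CODONS,
    SENSE_INDEX,
    STOP_CODONS,
    codon_diffs,
    pathway_averaged_counts,
    syn_site_fraction,
)

__all__ = ["CodonAlignment", "SubstitutionCounts", "count_substitutions", "ng86_dnds"]

GAP = "-"


@dataclass
class CodonAlignment:
    """In-frame aligned coding sequences of a locus's alleles.

    Length must be divisible by 3; internal stop codons are rejected (the
    marker genes analysed here contain none).  ``tree`` optionally carries
    an unrooted newick topology over the allele names (+ outgroup).
    """

    locus: str
    names: list[str]
    sequences: list[str]
    tree: str | None = None

    def __post_init__(self) -> None:
        if len(self.names) != len(self.sequences):
            raise ValueError("names and sequences differ in number")
        if not self.sequences:
            raise ValueError("empty alignment")
        L = len(self.sequences[0])
        if any(len(s) != L for s in self.sequences):
            raise ValueError("ragged alignment")
        if L % 3 != 0:
            raise ValueError(f"alignment length {L} not divisible by 3")
        self.sequences = [s.upper() for s in self.sequences]
        for name, seq in zip(self.names, self.sequences):
            for j in range(0, L - 3, 3):  # terminal stop permitted
                codon = seq[j : j + 3]
                if codon in STOP_CODONS:
                    raise ValueError(
                        f"internal stop codon {codon} in {name} at codon index {j // 3}"
                    )

    @property
    def n_codons(self) -> int:
        return len(self.sequences[0]) // 3

    def codon_column(self, j: int) -> list[str]:
        return [s[3 * j : 3 * j + 3] for s in self.sequences]

    def complete_deletion_columns(self) -> list[int]:
        """Codon columns free of gaps and ambiguity in every sequence."""
        keep = []
        for j in range(self.n_codons):
            col = self.codon_column(j)
            if all(c in SENSE_INDEX for c in col):
                keep.append(j)
        return keep


@dataclass
class SubstitutionCounts:
    n_synonymous: float
    n_nonsynonymous: float
    n_indel_events: int
    n_codons_used: int
    n_codons_excluded: int
    per_column: list = field(default_factory=list)  # (codon index, syn, nonsyn)


def _mst_edges(codons: list[str]) -> list[tuple[str, str]]:
    """Minimum spanning tree over distinct codons, edge weight = number of
    differing positions; Kruskal with deterministic (weight, lexicographic)
    tie-breaking so counting is input-order invariant."""
    nodes = sorted(set(codons))
    edges = sorted(
        (len(codon_diffs(a, b)), a, b)
        for i, a in enumerate(nodes)
        for b in nodes[i + 1 :]
    )
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    mst = []
    for _, a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            mst.append((a, b))
    return mst


def _indel_events(sequences: list[str]) -> int:
    """Distinct gap-run intervals: a contiguous run of gap columns present
    in at least one but not every sequence counts as one indel event."""
    runs = set()
    for seq in sequences:
        start = None
        for i, c in enumerate(seq + "X"):  # sentinel flushes a trailing run
            if c == GAP:
                if start is None:
                    start = i
            elif start is not None:
                runs.add((start, i))
                start = None
    # a run shared by all sequences is an alignment artefact, not an event
    shared = {
        run for run in runs
        if all(all(s[i] == GAP for i in range(*run)) for s in sequences)
    }
    return len(runs - shared)


def count_substitutions(aln: CodonAlignment) -> SubstitutionCounts:
    """Column-wise minimum-change substitution counts.

    For every polymorphic codon column the distinct observed codons are
    connected by a minimum spanning tree on the codon graph (single
    nucleotide steps); each MST edge contributes its pathway-averaged
    synonymous / non-synonymous step counts.  Codon columns containing a
    gap or ambiguity in any sequence are excluded (complete deletion).
    Indel events are contiguous gap runs.
    """
    if len(aln.sequences) < 2:
        raise ValueError("need at least two sequences")
    used = aln.complete_deletion_columns()
    syn = nonsyn = 0.0
    per_column = []
    for j in used:
        col = aln.codon_column(j)
        if len(set(col)) == 1:
            continue
        s_col = n_col = 0.0
        for a, b in _mst_edges(col):
            s, n = pathway_averaged_counts(a, b)
            s_col += s
            n_col += n
        syn += s_col
        nonsyn += n_col
        per_column.append((j, s_col, n_col))
    return SubstitutionCounts(
        n_synonymous=syn,
        n_nonsynonymous=nonsyn,
        n_indel_events=_indel_events(aln.sequences),
        n_codons_used=len(used),
        n_codons_excluded=aln.n_codons - len(used),
        per_column=per_column,
    )


def ng86_dnds(a: str, b: str) -> tuple[float | None, float | None, float | None]:
    """Nei-Gojobori (1986) dN, dS and omega for one aligned sequence pair.

    Sites are counted by codon degeneracy (averaged over the two
    sequences), differences by pathway averaging, and both proportions are
    Jukes-Cantor corrected.  Returns ``(dN, dS, omega)``; ``omega`` is None
    when dS = 0 (and dN, dS are None for saturated proportions p >= 3/4,
    which raise instead).
    """
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    if len(a) % 3 != 0:
        raise ValueError("length not divisible by 3")
    a, b = a.upper(), b.upper()
    S_sites = N_sites = 0.0
    Sd = Nd = 0.0
    n_codons = 0
    for j in range(0, len(a), 3):
        ca, cb = a[j : j + 3], b[j : j + 3]
        if ca not in SENSE_INDEX or cb not in SENSE_INDEX:
            continue  # gap/ambiguous/stop codon: excluded
        n_codons += 1
        s_a, s_b = syn_site_fraction(ca), syn_site_fraction(cb)
        S_sites += (s_a + s_b) / 2
        N_sites += 3 - (s_a + s_b) / 2
        s, n = pathway_averaged_counts(ca, cb)
        Sd += s
        Nd += n
    if n_codons == 0:
        raise ValueError("no comparable codons")

    def jc(p: float) -> float:
        if p == 0:
            return 0.0
        if p >= 0.75:
            raise ValueError(f"proportion {p:.3f} >= 3/4: beyond Jukes-Cantor correction")
        return -0.75 * math.log(1 - 4 * p / 3)

    pS = Sd / S_sites if S_sites > 0 else 0.0
    pN = Nd / N_sites if N_sites > 0 else 0.0
    dS = jc(pS)
    dN = jc(pN)
    omega = dN / dS if dS > 0 else None
    return dN, dS, omega
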
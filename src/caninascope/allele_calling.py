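"""Allele calling from cloned PCR sequences.

Cloned amplicons of a polyploid locus sample the individual alleles one at a
time, but carry PCR/sequencing errors and occasional PCR-recombination
chimeras.  This module collapses clone alignments into allele consensus
sequences (single-linkage clustering with a small intra-allele difference
budget, mirroring the pragmatic lumping of near-identical sub-clades),
screens clones for chimeric mosaics of two allele consensi, measures
pairwise divergence, and discovers diagnostic SNPs suitable for
pyrosequencing allele-frequency assays.

All coordinates are 0-based, half-open alignment columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pyroseq_sim import SNPAssay

__all__ = [
    "CloneAlignment",
    "AlleleSet",
    "ChimeraReport",
    "collapse_clones",
    "detect_chimeras",
    "pairwise_divergence",
    "find_diagnostic_snps",
]

GAP = "-"
_IUPAC = set("ACGTRYSWKMBDHVN-")

# minimal IUPAC ambiguity lookup for consensus ties
_AMBIG = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


@dataclass
class CloneAlignment:
    """Aligned cloned sequences of one locus plus a coding mask.

    ``coding_mask`` lists in-frame alignment columns as 0-based half-open
    intervals; their total length must be divisible by 3.
    """

    locus: str
    names: list[str]
    sequences: list[str]
    individuals: list[str] = field(default_factory=list)
    coding_mask: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("empty alignment")
        L = len(self.sequences[0])
        if any(len(s) != L for s in self.sequences):
            raise ValueError("ragged alignment: sequences differ in length")
        self.sequences = [s.upper() for s in self.sequences]
        bad = set("".join(self.sequences)) - _IUPAC
        if bad:
            raise ValueError(f"non-IUPAC characters in alignment: {sorted(bad)}")
        if not self.individuals:
            self.individuals = [""] * len(self.names)
        if self.coding_mask:
            total = sum(e - s for s, e in self.coding_mask)
            if total % 3 != 0:
                raise ValueError("coding mask length not divisible by 3")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def coding_columns(self) -> list[int]:
        cols: list[int] = []
        for s, e in self.coding_mask:
            cols.extend(range(s, e))
        return cols


@dataclass
class AlleleSet:
    """Collapsed alleles of a locus: label -> consensus, with clone support."""

    locus: str
    consensi: dict
    support: dict  # label -> clone count
    source_individuals: dict  # label -> sorted list of individuals
    singletons: list  # clone names excluded as putative PCR-error singletons

    @property
    def labels(self) -> list[str]:
        return list(self.consensi)


@dataclass
class ChimeraReport:
    clone: str
    verdict: str  # clean | chimeric
    parents: tuple | None = None  # (left parent, right parent)
    breakpoint: tuple | None = None  # 0-based half-open column interval
    score: int = 0  # mismatch improvement of mosaic over best single parent


def _diff_events(a: str, b: str) -> int:
    """Substitutions + contiguous-indel events between two aligned rows.

    A run of columns gapped in exactly one of the two sequences counts as a
    single indel event; columns gapped in both are ignored.
    """
    subs = 0
    indels = 0
    in_gap = False
    for ca, cb in zip(a, b):
        if ca == GAP and cb == GAP:
            in_gap = False
            continue
        if (ca == GAP) != (cb == GAP):
            if not in_gap:
                indels += 1
                in_gap = True
            continue
        in_gap = False
        if ca != cb:
            subs += 1
    return subs + indels


def pairwise_divergence(a: str, b: str, region: str = "whole",
                        coding_mask: list[tuple[int, int]] | None = None) -> float:
    """Percent divergence between two aligned sequences.

    Columns with a gap in either sequence are excluded from both numerator
    and denominator.  ``region='coding'`` restricts to the coding mask.
    """
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    a, b = a.upper(), b.upper()
    if region == "coding":
        if coding_mask is None:
            raise ValueError("coding region requested but no mask given")
        cols = [i for s, e in coding_mask for i in range(s, e)]
        a = "".join(a[i] for i in cols)
        b = "".join(b[i] for i in cols)
    compared = 0
    mismatches = 0
    for ca, cb in zip(a, b):
        if ca == GAP or cb == GAP:
            continue
        compared += 1
        if ca != cb:
            mismatches += 1
    if compared == 0:
        return 0.0
    return 100.0 * mismatches / compared


def _consensus(seqs: list[str]) -> str:
    """Column-majority consensus; ties become IUPAC ambiguity codes."""
    out = []
    for col in zip(*seqs):
        counts: dict[str, int] = {}
        for c in col:
            counts[c] = counts.get(c, 0) + 1
        best = max(counts.values())
        winners = sorted(c for c, n in counts.items() if n == best)
        if len(winners) == 1:
            out.append(winners[0])
        elif GAP in winners:
            out.append(GAP)  # gap-vs-base tie: keep the gap (conservative)
        else:
            out.append(_AMBIG.get(frozenset(winners), "N"))
    return "".join(out)


def collapse_clones(
    aln: CloneAlignment, max_intra_allele_diff: int = 4, min_clones: int = 2
) -> AlleleSet:
    """Collapse clones into alleles by single-linkage clustering.

    Clones within ``max_intra_allele_diff`` difference events (substitutions
    plus contiguous-indel events) are linked into one allele; clusters with
    fewer than ``min_clones`` members are excluded as putative PCR-error
    singletons but reported.  Consensus is by column majority.  Output is
    independent of input order: clusters are labelled ``<locus>-1, -2, ...``
    in order of decreasing support, ties broken by first clone name.
    """
    n = len(aln.sequences)
    # union-find over clones
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _diff_events(aln.sequences[i], aln.sequences[j]) <= max_intra_allele_diff:
                parent[find(i)] = find(j)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)

    members = sorted(
        clusters.values(),
        key=lambda idx: (-len(idx), min(aln.names[i] for i in idx)),
    )
    consensi: dict[str, str] = {}
    support: dict[str, int] = {}
    sources: dict[str, list[str]] = {}
    singletons: list[str] = []
    label_no = 0
    for idx in members:
        if len(idx) < min_clones:
            singletons.extend(sorted(aln.names[i] for i in idx))
            continue
        label_no += 1
        label = f"{aln.locus}-{label_no}"
        consensi[label] = _consensus([aln.sequences[i] for i in idx])
        support[label] = len(idx)
        sources[label] = sorted({aln.individuals[i] for i in idx if aln.individuals[i]})
    return AlleleSet(aln.locus, consensi, support, sources, singletons)


def _mismatches(a: str, b: str, cols) -> int:
    return sum(1 for i in cols if a[i] != b[i] and a[i] != GAP and b[i] != GAP)


def detect_chimeras(
    aln: CloneAlignment,
    alleles: AlleleSet,
    min_improvement: int = 3,
    min_flank_sites: int = 1,
) -> list[ChimeraReport]:
    """Screen each clone for a two-parent single-breakpoint PCR chimera.

    For every ordered allele pair and breakpoint the mosaic
    parent1[:bp] + parent2[bp:] is scored by mismatches to the clone; a
    clone is called chimeric when the best mosaic improves on the best
    single parent by at least ``min_improvement`` mismatches and each flank
    matches its parent at >= ``min_flank_sites`` sites diagnostic between
    the two parents.  The reported breakpoint interval spans the columns
    between the last left-supporting and first right-supporting diagnostic
    site (the breakpoint cannot be localized more finely).
    """
    labels = alleles.labels
    if len(labels) < 2:
        raise ValueError("need at least two alleles to screen for chimeras")
    L = aln.length
    cols = range(L)
    reports = []
    for name, seq in zip(aln.names, aln.sequences):
        single = {lab: _mismatches(seq, alleles.consensi[lab], cols) for lab in labels}
        best_single = min(single.values())
        best = None  # (mosaic mismatches, parents, breakpoint interval)
        for p1 in labels:
            for p2 in labels:
                if p1 == p2:
                    continue
                c1, c2 = alleles.consensi[p1], alleles.consensi[p2]
                diag = [
                    i for i in cols
                    if c1[i] != c2[i] and GAP not in (c1[i], c2[i]) and seq[i] != GAP
                ]
                if len(diag) < 2 * min_flank_sites:
                    continue
                # prefix[j] = clone-vs-p1 mismatches among first j diagnostic sites
                m1 = np.array([seq[i] != c1[i] for i in diag], dtype=int)
                m2 = np.array([seq[i] != c2[i] for i in diag], dtype=int)
                shared = _mismatches(seq, c1, [i for i in cols if c1[i] == c2[i]])
                pre1 = np.concatenate([[0], np.cumsum(m1)])
                suf2 = np.concatenate([[0], np.cumsum(m2[::-1])])[::-1]
                # breakpoint after diagnostic site j (j = min_flank..len-min_flank)
                for j in range(min_flank_sites, len(diag) - min_flank_sites + 1):
                    mosaic = shared + pre1[j] + (suf2[j])
                    left_ok = (j - pre1[j]) >= min_flank_sites
                    right_ok = (len(diag) - j - suf2[j]) >= min_flank_sites
                    if not (left_ok and right_ok):
                        continue
                    if best is None or mosaic < best[0]:
                        lo = diag[j - 1] + 1
                        hi = diag[j] if j < len(diag) else L
                        best = (mosaic, (p1, p2), (lo, hi))
        if best is not None and best[0] <= best_single - min_improvement:
            reports.append(
                ChimeraReport(name, "chimeric", best[1], best[2], best_single - best[0])
            )
        else:
            reports.append(ChimeraReport(name, "clean", score=0))
    return reports


def find_diagnostic_snps(
    alleles: AlleleSet,
    coding_mask: list[tuple[int, int]],
    carrier_max: int | None = None,
    flank: int = 3,
) -> list[SNPAssay]:
    """Discover pyrosequencing-suitable diagnostic SNPs.

    A coding column is emitted when it is gap- and ambiguity-free in every
    allele, the base partitions the alleles into a carrier set of size
    <= ``carrier_max`` versus the rest, and the ``flank`` columns either
    side are monomorphic (a proxy for a clean pyrosequencing dispensation
    context).  Carrier sets of size >= 2 are allowed: a SNP shared by two
    closely related alleles still quantifies their combined frequency.
    """
    labels = alleles.labels
    if len(labels) < 2:
        raise ValueError("need at least two alleles")
    seqs = [alleles.consensi[lab] for lab in labels]
    L = len(seqs[0])
    coding = set()
    for s, e in coding_mask:
        coding.update(range(s, e))

    def clean(i: int) -> bool:
        return all(s[i] in "ACGT" for s in seqs)

    def monomorphic(i: int) -> bool:
        return len({s[i] for s in seqs}) == 1 and clean(i)

    out: list[SNPAssay] = []
    n_assay = 0
    cmax = len(labels) - 1 if carrier_max is None else carrier_max
    for i in sorted(coding):
        if i >= L or not clean(i):
            continue
        col = {lab: alleles.consensi[lab][i] for lab in labels}
        bases = set(col.values())
        if len(bases) != 2:
            continue  # need a clean biallelic partition
        lo, hi = max(0, i - flank), min(L, i + flank + 1)
        if not all(monomorphic(j) for j in range(lo, hi) if j != i):
            continue
        # the diagnostic base is the one carried by fewer alleles
        by_base = {
            base: frozenset(lab for lab, b in col.items() if b == base) for base in bases
        }
        base = min(sorted(by_base), key=lambda b: len(by_base[b]))
        carriers = by_base[base]
        if 1 <= len(carriers) <= cmax:
            n_assay += 1
            out.append(
                SNPAssay(
                    assay_id=f"{alleles.locus}_SNP{n_assay}",
                    locus=alleles.locus,
                    position=i,
                    diagnostic_base=base,
                    carrier_alleles=carriers,
                )
            )
    return out
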
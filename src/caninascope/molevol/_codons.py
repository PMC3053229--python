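"""Codon-level lookup tables built on the universal genetic code."""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

NUCS = "TCAG"
CODONS = ["".join(c) for c in itertools.product(NUCS, repeat=3)]

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = [c for c in CODONS if c not in STOP_CODONS]  # 61
SENSE_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}

AA_OF = dict(_TABLE.forward_table)  # sense codon -> amino acid

TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def is_transition(a: str, b: str) -> bool:
    return frozenset((a, b)) in TRANSITIONS


def codon_diffs(c1: str, c2: str) -> list[int]:
    """Positions (0..2) at which two codons differ."""
    return [i for i in range(3) if c1[i] != c2[i]]


def is_synonymous(c1: str, c2: str) -> bool:
    """Single-step codon change classification (both must be sense)."""
    return AA_OF[c1] == AA_OF[c2]


@lru_cache(maxsize=None)
def pathways(c1: str, c2: str, allow_stops: bool = False) -> list[list[tuple[str, str]]]:
    """All mutational pathways between two codons as lists of single-step
    (from, to) codon pairs, one pathway per ordering of the differing
    positions.  Pathways passing through a stop codon are dropped unless
    none survive (then all are kept), following the usual pathway-averaging
    convention.
    """
    diffs = codon_diffs(c1, c2)
    paths = []
    for order in itertools.permutations(diffs):
        cur = c1
        steps = []
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS and nxt != c2:
                through_stop = True
            steps.append((cur, nxt))
            cur = nxt
        paths.append((through_stop, steps))
    clean = [steps for through, steps in paths if not through]
    if clean and not allow_stops:
        return clean
    return [steps for _, steps in paths]


def pathway_averaged_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) step counts averaged over pathways."""
    if c1 == c2:
        return 0.0, 0.0
    syn = nonsyn = 0.0
    paths = pathways(c1, c2)
    for steps in paths:
        for a, b in steps:
            if a in STOP_CODONS or b in STOP_CODONS:
                nonsyn += 1  # stop-involving step counted as non-synonymous
            elif is_synonymous(a, b):
                syn += 1
            else:
                nonsyn += 1
    n = len(paths)
    return syn / n, nonsyn / n


@lru_cache(maxsize=None)
def syn_site_fraction(codon: str) -> float:
    """NG86 synonymous site count of one codon (0..3).

    For each position, the fraction of the three possible nucleotide
    changes that are synonymous; changes creating a stop codon count as
    non-synonymous.
    """
    s = 0.0
    for pos in range(3):
        syn = 0
        for nuc in NUCS:
            if nuc == codon[pos]:
                continue
            alt = codon[:pos] + nuc + codon[pos + 1:]
            if alt not in STOP_CODONS and is_synonymous(codon, alt):
                syn += 1
        s += syn / 3.0
    return s


def f3x4_frequencies(codon_indices: np.ndarray) -> np.ndarray:
    """F3x4 sense-codon frequencies from observed codons.

    Position-specific nucleotide frequencies are multiplied per codon; stop
    codons are excluded and the 61 sense frequencies renormalized.  A small
    pseudo-frequency guards against unobserved nucleotides.
    """
    pos_freq = np.full((3, 4), 0.01)
    nuc_idx = {n: i for i, n in enumerate(NUCS)}
    flat = codon_indices.ravel()
    for ci in flat:
        codon = SENSE_CODONS[ci]
        for pos in range(3):
            pos_freq[pos, nuc_idx[codon[pos]]] += 1
    pos_freq /= pos_freq.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            pos_freq[0, nuc_idx[c[0]]] * pos_freq[1, nuc_idx[c[1]]] * pos_freq[2, nuc_idx[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    return pi / pi.sum()
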
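"""Tajima's relative rate test with FDR correction over allele pairs.

For two ingroup sequences and an outgroup, sites where only sequence 1
differs from the outgroup (m1) or only sequence 2 differs (m2) are
informative about lineage-specific substitutions; under equal rates
m1 and m2 have the same expectation and

    chi2 = (m1 - m2)^2 / (m1 + m2)    ~  chi-square(1).

The batch wrapper runs every ingroup pair against the outgroup and applies
Benjamini-Hochberg correction across pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from ..ase import benjamini_hochberg

__all__ = ["RRTResult", "tajima_rrt", "tajima_rrt_batch"]

_VALID = set("ACGT")


@dataclass
class RRTResult:
    pair: tuple
    m1: int  # sites where only sequence 1 differs from the outgroup
    m2: int
    statistic: float
    p_value: float
    p_adjusted: float | None = None
    tested: bool = True  # False when m1 + m2 = 0 (p = 1 by convention)

    def verdict(self, alpha: float = 0.05) -> str:
        p = self.p_adjusted if self.p_adjusted is not None else self.p_value
        return "unequal-rates" if (self.tested and p < alpha) else "equal-rates"


def tajima_rrt(seq1: str, seq2: str, outgroup: str, pair=("seq1", "seq2")) -> RRTResult:
    """Tajima's 1D relative rate test on three aligned sequences.

    Columns with a gap or ambiguity in any of the three sequences are
    ignored.  With no informative sites (m1 + m2 = 0) no test is performed
    and p = 1 is returned, flagged via ``tested=False``.
    """
    if not (len(seq1) == len(seq2) == len(outgroup)):
        raise ValueError("all three sequences must be aligned to equal length")
    m1 = m2 = 0
    for a, b, o in zip(seq1.upper(), seq2.upper(), outgroup.upper()):
        if a not in _VALID or b not in _VALID or o not in _VALID:
            continue
        if a != o and b == o:
            m1 += 1
        elif b != o and a == o:
            m2 += 1
    if m1 + m2 == 0:
        return RRTResult(tuple(pair), 0, 0, 0.0, 1.0, tested=False)
    chi2 = (m1 - m2) ** 2 / (m1 + m2)
    p = float(stats.chi2.sf(chi2, df=1))
    return RRTResult(tuple(pair), m1, m2, float(chi2), p)


def tajima_rrt_batch(sequences: dict, outgroup_name: str) -> list[RRTResult]:
    """All ingroup pairs against the named outgroup, BH-adjusted."""
    if outgroup_name not in sequences:
        raise ValueError(f"outgroup {outgroup_name!r} not among sequences")
    out = sequences[outgroup_name]
    names = sorted(n for n in sequences if n != outgroup_name)
    results = [
        tajima_rrt(sequences[a], sequences[b], out, pair=(a, b))
        for i, a in enumerate(names)
        for b in names[i + 1 :]
    ]
    if results:
        adj = benjamini_hochberg([r.p_value for r in results])
        for r, q in zip(results, adj):
            r.p_adjusted = float(q)
    return results
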
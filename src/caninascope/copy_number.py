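"""Integer copy-number inference from genomic pyrosequencing fractions.

Under equal transmission, an allele subset carried in k of p chromosome
sets produces a diagnostic-base fraction of k/p in genomic DNA.  Given
gDNA replicate measurements for each assay of a locus, this module scores
every composition of the ploidy among the detected alleles (each detected
allele gets at least one copy) and reports the maximum-likelihood call with
the log-likelihood gap to the runner-up.

Likelihood: beta-binomial on diagnostic-base counts when read depths are
available, Gaussian on fractions (variance pooled across the locus's
replicates) when only fractions were recorded.

Alleles not covered by any assay (no usable diagnostic SNP existed) absorb
the residual copies, split as evenly as possible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pyroseq_sim import AssayNoise, SNPAssay

__all__ = ["CopyNumberCall", "enumerate_compositions", "infer_copy_numbers", "flag_anomalous_assays"]


@dataclass
class CopyNumberCall:
    """A per-individual copy-number call for one locus."""

    locus: str
    individual: str
    copies: dict  # allele -> integer copies, summing to the ploidy
    log_likelihood: float
    fitted_means: dict  # assay_id -> fitted gDNA fraction k/p
    runner_up_gap: float  # lnL(top) - lnL(second); inf if only one composition
    rank: int = 1
    ties: list = None  # compositions tied in likelihood with the call
    notes: str = ""

    @property
    def ploidy(self) -> int:
        return sum(self.copies.values())


def enumerate_compositions(n_alleles: int, ploidy: int) -> list[tuple[int, ...]]:
    """All vectors of positive integers of length ``n_alleles`` summing to
    ``ploidy``, in lexicographic order (C(ploidy-1, n_alleles-1) of them)."""
    if n_alleles < 1:
        raise ValueError("need at least one allele")
    if n_alleles > ploidy:
        raise ValueError(f"{n_alleles} alleles cannot each have >=1 of {ploidy} copies")

    out: list[tuple[int, ...]] = []

    def rec(prefix: tuple[int, ...], remaining: int, slots: int) -> None:
        if slots == 1:
            out.append(prefix + (remaining,))
            return
        for k in range(1, remaining - slots + 2):
            rec(prefix + (k,), remaining - k, slots - 1)

    rec((), ploidy, n_alleles)
    return out


def _loglik(frac: np.ndarray, depth: np.ndarray | None, mean: float,
            rho: float, sigma: float) -> float:
    """Log-likelihood of replicate fractions around ``mean``."""
    if depth is not None:
        counts = np.rint(frac * depth).astype(int)
        m = min(max(mean, 1e-6), 1 - 1e-6)
        if rho > 0:
            s = (1 - rho) / rho
            return float(stats.betabinom.logpmf(counts, depth, m * s, (1 - m) * s).sum())
        return float(stats.binom.logpmf(counts, depth, m).sum())
    return float(stats.norm.logpdf(frac, loc=mean, scale=sigma).sum())


def infer_copy_numbers(
    obs: pd.DataFrame,
    assays: list[SNPAssay],
    alleles: list[str],
    ploidy: int,
    noise: AssayNoise | None = None,
    individual: str | None = None,
) -> CopyNumberCall:
    """Maximum-likelihood composition call for one individual at one locus.

    ``obs`` is an observation table (gDNA rows are used); ``alleles`` lists
    every detected allele of the locus, assayed or not.  Compositions whose
    likelihood depends only on unassayed alleles are tied; residual copies
    among unassayed alleles are split as evenly as possible, remaining ties
    broken by allele label order (flagged in ``notes``).
    """
    noise = noise or AssayNoise()
    g = obs[obs["template"] == "gDNA"]
    if individual is not None:
        g = g[g["individual"] == individual]
    else:
        inds = g["individual"].unique()
        if len(inds) > 1:
            raise ValueError(
                "observations span several individuals; pass individual= "
                "(compositions are inferred per individual)"
            )
        individual = inds[0] if len(inds) else "NA"
    if g.empty:
        raise ValueError("no genomic observations to fit")
    assays = [a for a in assays if a.assay_id in set(g["assay_id"])]
    if not assays:
        raise ValueError("no assay has genomic observations")
    for a in assays:
        if not set(a.carrier_alleles) <= set(alleles):
            raise ValueError(f"assay {a.assay_id} carriers not a subset of alleles")
    locus = assays[0].locus

    per_assay = {}
    have_depth = g["depth"].notna().all()
    # pooled Gaussian scale across the locus (fractions-only data)
    if have_depth:
        sigma = None
    else:
        resid = g.groupby("assay_id")["fraction"].transform(lambda s: s - s.mean())
        sigma = float(max(resid.std(ddof=0), 1e-3))
    for a in assays:
        rows = g[g["assay_id"] == a.assay_id]
        frac = rows["fraction"].to_numpy(float)
        depth = rows["depth"].to_numpy(float).astype(int) if have_depth else None
        per_assay[a.assay_id] = (frac, depth)

    alleles = sorted(alleles)
    scored: list[tuple[float, tuple[int, ...]]] = []
    for comp in enumerate_compositions(len(alleles), ploidy):
        k_of = dict(zip(alleles, comp))
        ll = 0.0
        for a in assays:
            k = sum(k_of[x] for x in a.carrier_alleles)
            frac, depth = per_assay[a.assay_id]
            ll += _loglik(frac, depth, k / ploidy, noise.rho, sigma if sigma else 0.0)
        scored.append((ll, comp))

    scored.sort(key=lambda t: (-t[0], t[1]))
    best_ll = scored[0][0]
    tied = [comp for ll, comp in scored if np.isclose(ll, best_ll, atol=1e-9)]
    notes = ""
    if len(tied) > 1:
        # prefer the most even split of the residual among unassayed alleles,
        # then lexicographic order
        assayed = set().union(*(a.carrier_alleles for a in assays))
        unassayed_idx = [i for i, al in enumerate(alleles) if al not in assayed]

        def spread(comp: tuple[int, ...]) -> int:
            vals = [comp[i] for i in unassayed_idx]
            return (max(vals) - min(vals)) if vals else 0

        tied.sort(key=lambda c: (spread(c), c))
        notes = f"{len(tied)} compositions tied in likelihood; most-even residual split chosen"
    best = tied[0]
    # runner-up among strictly different likelihoods
    gap = np.inf
    for ll, comp in scored:
        if not np.isclose(ll, best_ll, atol=1e-9):
            gap = best_ll - ll
            break
    k_of = dict(zip(alleles, best))
    fitted = {
        a.assay_id: sum(k_of[x] for x in a.carrier_alleles) / ploidy for a in assays
    }
    return CopyNumberCall(
        locus=locus,
        individual=str(individual),
        copies=k_of,
        log_likelihood=best_ll,
        fitted_means=fitted,
        runner_up_gap=float(gap),
        ties=[dict(zip(alleles, c)) for c in tied],
        notes=notes,
    )


def flag_anomalous_assays(
    call: CopyNumberCall,
    obs: pd.DataFrame,
    noise: AssayNoise | None = None,
    z_threshold: float = 4.0,
) -> list[str]:
    """Assays whose mean gDNA fraction sits implausibly far from the fitted
    k/p mean (assay bias or a mis-specified carrier set).

    The deviation is scored in units of the noise standard deviation of the
    replicate mean under the beta-binomial model.
    """
    noise = noise or AssayNoise()
    g = obs[(obs["template"] == "gDNA") & (obs["individual"] == call.individual)]
    flagged = []
    for assay_id, mean in call.fitted_means.items():
        rows = g[g["assay_id"] == assay_id]
        if rows.empty:
            continue
        obs_mean = rows["fraction"].mean()
        n_rep = len(rows)
        N = noise.read_depth
        var1 = mean * (1 - mean) * (1 + (N - 1) * noise.rho) / N
        se = np.sqrt(var1 / n_rep)
        if se == 0:
            continue
        if abs(obs_mean - mean) / se > z_threshold:
            flagged.append(assay_id)
    return flagged
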
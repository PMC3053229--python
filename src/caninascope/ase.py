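"""Allele-specific transcription analysis.

The question: does an allele's share of the transcript pool (cDNA
diagnostic-base fraction) match its share of the genome (k copies out of
ploidy p)?  Equal per-copy transcription predicts identical gDNA and cDNA
fractions; deviations quantify allele-specific expression.

Three statistical pieces:

* :func:`fold_deviation` — observed cDNA mean relative to the copy-number
  null k/p, with a percentile-bootstrap confidence interval, reported in
  the "x-fold higher / x-fold lower" convention;
* :func:`glm_template_test` — the template (gDNA vs cDNA) contrast as a
  classical mixed-model ANOVA with individual as a random factor:
  F = MS(template) / MS(template x individual);
* :func:`anova_nuisance_test` — one-way ANOVA of cDNA fractions on a
  nuisance factor (bud stage or individual).

:func:`ase_report` ties them together per assay, grouping individuals that
share a genomic composition and splitting those that differ, with optional
Benjamini-Hochberg adjustment across the assays of a locus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .copy_number import CopyNumberCall
from .pyroseq_sim import SNPAssay

__all__ = [
    "ASEResult",
    "FoldDeviation",
    "fold_deviation",
    "glm_template_test",
    "anova_nuisance_test",
    "ase_report",
    "benjamini_hochberg",
    "results_to_frame",
]


@dataclass
class FoldDeviation:
    """Fold deviation of the cDNA mean from the copy-number null."""

    fold: float  # mean(cDNA)/expected; >1 over-, <1 under-transcribed
    direction: str  # up | down | null
    reported_fold: float  # fold if up, 1/fold if down (always >= 1)
    ci_low: float | None = None  # bootstrap CI on `fold`
    ci_high: float | None = None

    def describe(self) -> str:
        if self.direction == "null":
            return "at the copy-number expectation"
        word = "higher" if self.direction == "up" else "lower"
        return f"{self.reported_fold:.1f}-fold {word} than expected"


@dataclass
class ASEResult:
    assay_id: str
    locus: str
    individuals: tuple
    expected: float  # null fraction k/ploidy
    observed_cdna_mean: float
    fold: FoldDeviation
    p_value: float
    p_adjusted: float | None
    template_effect: float  # cDNA mean - gDNA mean (marginal over individuals)
    n_gdna: int
    n_cdna: int


def fold_deviation(
    cdna_fractions,
    expected: float,
    n_boot: int = 2000,
    seed: int | None = 0,
    ci: float = 0.95,
) -> FoldDeviation:
    """Fold deviation of mean cDNA fraction from the expected null fraction.

    ``fold = mean(cdna)/expected``; values above 1 are reported as
    "fold-higher", below 1 as the reciprocal "fold-lower", matching how
    transcription differences are conventionally phrased.  The CI is a
    seeded percentile bootstrap over replicates (omitted for < 2 values).
    """
    if not 0 < expected <= 1:
        raise ValueError("expected fraction must lie in (0, 1]")
    x = np.asarray(cdna_fractions, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one cDNA observation")
    fold = float(x.mean() / expected)
    if np.isclose(fold, 1.0):
        direction, reported = "null", 1.0
    elif fold > 1:
        direction, reported = "up", fold
    else:
        direction, reported = "down", 1.0 / fold
    lo = hi = None
    if x.size >= 2 and n_boot > 0:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, x.size, size=(n_boot, x.size))
        boots = x[idx].mean(axis=1) / expected
        alpha = (1 - ci) / 2
        lo, hi = (float(q) for q in np.quantile(boots, [alpha, 1 - alpha]))
    return FoldDeviation(fold, direction, reported, lo, hi)


def _two_way_anova(y: np.ndarray, template: np.ndarray, individual: np.ndarray):
    """Classical two-way ANOVA sums of squares (template x individual) on an
    unbalanced layout, by proportional (weighted-means) decomposition.

    Returns (MS_template, MS_interaction, df_template, df_interaction).
    """
    templates = np.unique(template)
    individuals = np.unique(individual)
    grand = y.mean()
    n = y.size
    # cell means
    ss_t = 0.0
    for t in templates:
        sel = template == t
        ss_t += sel.sum() * (y[sel].mean() - grand) ** 2
    ss_i = 0.0
    for i in individuals:
        sel = individual == i
        ss_i += sel.sum() * (y[sel].mean() - grand) ** 2
    ss_cells = 0.0
    for t in templates:
        for i in individuals:
            sel = (template == t) & (individual == i)
            if sel.sum() == 0:
                raise ValueError(f"empty cell: template={t}, individual={i}")
            ss_cells += sel.sum() * (y[sel].mean() - grand) ** 2
    ss_ti = ss_cells - ss_t - ss_i
    df_t = len(templates) - 1
    df_ti = (len(templates) - 1) * (len(individuals) - 1)
    return ss_t / df_t, ss_ti / max(df_ti, 1), df_t, df_ti


def glm_template_test(design: pd.DataFrame, assay_id: str | None = None):
    """Mixed-model ANOVA contrast of gDNA vs cDNA fractions.

    Template is a fixed factor, individual a random factor; following the
    expected-mean-squares rule the template effect is tested against the
    template x individual interaction:
    ``F = MS(template) / MS(template x individual)`` on
    (1, (n_individuals - 1)) degrees of freedom.

    With a single individual the interaction vanishes and the function
    falls back to Welch's two-sample t-test with a warning.

    Returns ``(p_value, effect)`` where ``effect`` is the difference of
    marginal template means (cDNA - gDNA).
    """
    d = design if assay_id is None else design[design["assay_id"] == assay_id]
    templates = set(d["template"])
    if templates != {"gDNA", "cDNA"}:
        raise ValueError(f"need both templates, found {sorted(templates)}")
    y = d["fraction"].to_numpy(float)
    template = d["template"].to_numpy(str)
    individual = d["individual"].to_numpy(str)
    effect = float(y[template == "cDNA"].mean() - y[template == "gDNA"].mean())
    if np.ptp(y) == 0:
        return 1.0, 0.0  # all-constant response: no evidence of any effect
    n_ind = len(np.unique(individual))
    if n_ind < 2:
        warnings.warn(
            "single individual: falling back to Welch's t-test "
            "(random-factor model needs >= 2 individuals)",
            stacklevel=2,
        )
        t = stats.ttest_ind(
            y[template == "cDNA"], y[template == "gDNA"], equal_var=False
        )
        return float(t.pvalue), effect
    ms_t, ms_ti, df_t, df_ti = _two_way_anova(y, template, individual)
    if ms_ti == 0:
        # zero interaction variance: identical per-individual contrasts.
        # F=0 convention when the template effect is also zero.
        return (1.0 if ms_t == 0 else 0.0), effect
    F = ms_t / ms_ti
    p = float(stats.f.sf(F, df_t, df_ti))
    return p, effect


def anova_nuisance_test(design: pd.DataFrame, factor: str, assay_id: str | None = None) -> float:
    """One-way ANOVA of cDNA fractions on ``factor`` (bud_stage|individual).

    Returns the F-test p-value; degenerate inputs (a single level, or zero
    variance everywhere) return NaN with a warning rather than a p-value.
    """
    if factor not in ("bud_stage", "individual"):
        raise ValueError("factor must be 'bud_stage' or 'individual'")
    d = design if assay_id is None else design[design["assay_id"] == assay_id]
    d = d[d["template"] == "cDNA"]
    groups = [g["fraction"].to_numpy(float) for _, g in d.groupby(factor)]
    if len(groups) < 2:
        raise ValueError(f"factor {factor!r} has fewer than two levels")
    if np.ptp(np.concatenate(groups)) == 0:
        warnings.warn("zero variance in response: no test performed", stacklevel=2)
        return float("nan")
    F, p = stats.f_oneway(*groups)
    return float(p)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def ase_report(
    calls: list[CopyNumberCall],
    design: pd.DataFrame,
    assays: list[SNPAssay],
    adjust: bool = True,
    seed: int = 0,
) -> list[ASEResult]:
    """Per-assay allele-specific-transcription summary for one locus.

    Individuals sharing the same genomic composition at an assay's carrier
    set are pooled into one test; individuals with a different composition
    (hence a different null fraction) are tested separately.  Assays without
    a copy-number call for their carriers raise; assays missing a template
    in the data are skipped with a warning.
    """
    calls_by_ind = {c.individual: c for c in calls}
    results: list[ASEResult] = []
    for assay in assays:
        d = design[design["assay_id"] == assay.assay_id]
        if d.empty or set(d["template"]) != {"gDNA", "cDNA"}:
            warnings.warn(f"assay {assay.assay_id}: missing template rows; skipped", stacklevel=2)
            continue
        # group individuals by their null fraction for this assay
        groups: dict[float, list[str]] = {}
        for ind in sorted(d["individual"].unique()):
            if ind not in calls_by_ind:
                raise ValueError(f"no copy-number call for individual {ind!r}")
            call = calls_by_ind[ind]
            missing = set(assay.carrier_alleles) - set(call.copies)
            if missing:
                raise ValueError(
                    f"assay {assay.assay_id}: no call for carriers {sorted(missing)}"
                )
            k = sum(call.copies[a] for a in assay.carrier_alleles)
            expected = k / call.ploidy
            groups.setdefault(expected, []).append(ind)
        for expected, inds in sorted(groups.items()):
            sub = d[d["individual"].isin(inds)]
            cdna = sub[sub["template"] == "cDNA"]["fraction"].to_numpy(float)
            gdna = sub[sub["template"] == "gDNA"]["fraction"].to_numpy(float)
            fold = fold_deviation(cdna, expected, seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p, effect = glm_template_test(sub)
            results.append(
                ASEResult(
                    assay_id=assay.assay_id,
                    locus=assay.locus,
                    individuals=tuple(inds),
                    expected=expected,
                    observed_cdna_mean=float(cdna.mean()),
                    fold=fold,
                    p_value=p,
                    p_adjusted=None,
                    template_effect=effect,
                    n_gdna=len(gdna),
                    n_cdna=len(cdna),
                )
            )
    if adjust and results:
        adj = benjamini_hochberg([r.p_value for r in results])
        for r, q in zip(results, adj):
            r.p_adjusted = float(q)
    return results


def results_to_frame(results: list[ASEResult]) -> pd.DataFrame:
    """Flatten ASE results into a tidy table."""
    return pd.DataFrame(
        [
            {
                "assay_id": r.assay_id,
                "locus": r.locus,
                "individuals": ",".join(r.individuals),
                "expected": r.expected,
                "observed_cdna_mean": r.observed_cdna_mean,
                "fold": r.fold.fold,
                "direction": r.fold.direction,
                "reported_fold": r.fold.reported_fold,
                "fold_ci_low": r.fold.ci_low,
                "fold_ci_high": r.fold.ci_high,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
                "template_effect": r.template_effect,
                "n_gdna": r.n_gdna,
                "n_cdna": r.n_cdna,
            }
            for r in results
        ]
    )
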
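"""Synthetic pyrosequencing allele-frequency data.

Pyrosequencing of a diagnostic SNP reports the fraction of the
allele-specific base in a PCR product amplified from a template pool
(genomic DNA or cDNA).  Under equal transmission, an allele carried in k of
the p chromosome sets contributes k/p of the genomic template, so gDNA
fractions sit at the copy-number null k/p (0.2 / 0.4 / 0.6 for k = 1, 2, 3
in pentaploids).  cDNA fractions shift away from k/p when per-copy
transcription rates differ between alleles.

Replicate-to-replicate technical scatter is modelled as beta-binomial
counts on a nominal read depth: the replicate mean is the true (possibly
assay-biased) fraction and the intra-class correlation ``rho`` captures
extra-binomial variance from pipetting, PCR and instrument chemistry.

Two cDNA generation modes are provided:

* composition mode — a single :class:`ExpressionProfile` of per-copy rates
  makes all assays of a locus mutually consistent;
* per-assay target mode — each assay gets its own true cDNA fraction,
  mirroring real pyrosequencing assays whose independent PCRs and primer
  chemistries carry independent biases (so measured fractions of one locus
  need not sum to 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SNPAssay",
    "ExpressionProfile",
    "AssayNoise",
    "FrequencyObservation",
    "ExperimentDesign",
    "expected_frequency",
    "cdna_expected_frequency",
    "simulate_assay",
    "simulate_experiment",
    "observations_to_frame",
]

OBSERVATION_COLUMNS = [
    "assay_id",
    "locus",
    "template",
    "individual",
    "bud_stage",
    "replicate",
    "fraction",
    "depth",
]


@dataclass(frozen=True)
class SNPAssay:
    """A diagnostic site: an alignment column whose base separates a carrier
    subset of alleles from the rest of the locus's alleles."""

    assay_id: str
    locus: str
    position: int  # 0-based column in the coding alignment
    diagnostic_base: str
    carrier_alleles: frozenset

    def __post_init__(self) -> None:
        if not self.carrier_alleles:
            raise ValueError(f"assay {self.assay_id}: empty carrier set")
        object.__setattr__(self, "carrier_alleles", frozenset(self.carrier_alleles))


@dataclass(frozen=True)
class ExpressionProfile:
    """Relative per-copy transcription rates, allele -> e_a > 0.

    Only ratios matter: rescaling every rate by a common factor leaves all
    expected cDNA fractions unchanged.  The equal-transcription null is all
    rates equal.
    """

    rates: dict

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.rates.values()):
            raise ValueError("per-copy transcription rates must be > 0")

    @classmethod
    def null(cls, alleles) -> "ExpressionProfile":
        return cls({a: 1.0 for a in alleles})


@dataclass(frozen=True)
class AssayNoise:
    """Technical noise of one pyrosequencing determination.

    ``read_depth`` is the nominal number of template molecules scored per
    replicate (``None`` is the infinite-depth limit: with ``rho=0`` the
    reported fraction is exactly the true mean); ``rho`` the beta-binomial
    intra-class correlation (rho=0 degenerates to binomial);
    ``assay_bias`` a multiplicative bias applied to the true fraction
    before sampling (clipped into [0, 1]).
    """

    read_depth: int | None = 500
    rho: float = 0.005
    assay_bias: float = 1.0

    def __post_init__(self) -> None:
        if self.read_depth is not None and self.read_depth < 1:
            raise ValueError("read_depth must be >= 1")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        if self.assay_bias <= 0:
            raise ValueError("assay_bias must be > 0")


@dataclass(frozen=True)
class FrequencyObservation:
    """One pyrosequencing measurement of a diagnostic-base fraction."""

    assay_id: str
    locus: str
    template: str  # gDNA | cDNA
    individual: str
    bud_stage: str  # small | large | NA
    replicate: int
    fraction: float
    depth: int | None = None

    def __post_init__(self) -> None:
        if self.template not in ("gDNA", "cDNA"):
            raise ValueError(f"unknown template {self.template!r}")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"fraction {self.fraction} outside [0, 1]")
        if self.template == "gDNA" and self.bud_stage != "NA":
            raise ValueError("gDNA observations carry no bud stage (use 'NA')")


@dataclass(frozen=True)
class ExperimentDesign:
    """Sampling design: which individuals, bud stages and replicate counts.

    The default mirrors the assay layout used for dogrose flower buds:
    two gDNA PCR replicates per individual and three cDNA PCR replicates
    per bud stage (small and large) per individual.
    """

    individuals: tuple = ("H13", "H19", "H20")
    bud_stages: tuple = ("small", "large")
    n_gdna_replicates: int = 2
    n_cdna_replicates: int = 3


def expected_frequency(carrier_copies: int, ploidy: int) -> float:
    """Expected gDNA diagnostic-base fraction for an allele subset carried
    in ``carrier_copies`` of ``ploidy`` chromosome sets: exactly k/p."""
    if not 1 <= carrier_copies <= ploidy:
        raise ValueError(f"carrier copies {carrier_copies} outside [1, {ploidy}]")
    return carrier_copies / ploidy


def cdna_expected_frequency(copy_numbers: dict, rates: ExpressionProfile, carriers) -> float:
    """Expected cDNA diagnostic-base fraction under per-copy rates.

    Each of the k_a genomic copies of allele a contributes transcripts at
    rate e_a, so the carrier set's share of the transcript pool is
    (sum over carriers of k_a * e_a) / (sum over all alleles of k_b * e_b).
    Reduces to k/p when all rates are equal.
    """
    carriers = set(carriers)
    unknown = carriers - set(copy_numbers)
    if unknown:
        raise ValueError(f"carrier alleles absent from copy numbers: {sorted(unknown)}")
    total = sum(k * rates.rates[a] for a, k in copy_numbers.items())
    part = sum(copy_numbers[a] * rates.rates[a] for a in carriers)
    return part / total


def _betabinom_counts(
    rng: np.random.Generator, n_draws: int, depth: int, mean: float, rho: float
) -> np.ndarray:
    """Beta-binomial counts with mean ``depth*mean`` and ICC ``rho``."""
    if mean <= 0.0:
        return np.zeros(n_draws, dtype=int)
    if mean >= 1.0:
        return np.full(n_draws, depth, dtype=int)
    if rho == 0.0:
        return rng.binomial(depth, mean, size=n_draws)
    s = (1.0 - rho) / rho  # beta concentration: a+b
    p = rng.beta(mean * s, (1.0 - mean) * s, size=n_draws)
    return rng.binomial(depth, p)


def simulate_assay(
    true_fraction: float,
    noise: AssayNoise,
    n_replicates: int,
    seed: int | np.random.Generator,
    *,
    assay: SNPAssay | None = None,
    template: str = "cDNA",
    individual: str = "sim",
    bud_stage: str | None = None,
) -> list[FrequencyObservation]:
    """Simulate replicate fraction measurements of one assay.

    Each replicate is one beta-binomial draw of diagnostic-base counts at
    the nominal read depth; the reported fraction is count/depth.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mean = float(np.clip(true_fraction * noise.assay_bias, 0.0, 1.0))
    if noise.read_depth is None:
        if noise.rho == 0.0 or mean in (0.0, 1.0):
            fractions = [mean] * n_replicates
        else:
            s = (1.0 - noise.rho) / noise.rho
            fractions = rng.beta(mean * s, (1.0 - mean) * s, size=n_replicates).tolist()
    else:
        counts = _betabinom_counts(rng, n_replicates, noise.read_depth, mean, noise.rho)
        fractions = [int(c) / noise.read_depth for c in counts]
    stage = bud_stage if bud_stage is not None else "NA"
    assay_id = assay.assay_id if assay is not None else "assay"
    locus = assay.locus if assay is not None else "locus"
    return [
        FrequencyObservation(
            assay_id=assay_id,
            locus=locus,
            template=template,
            individual=individual,
            bud_stage=stage,
            replicate=r,
            fraction=f,
            depth=noise.read_depth,
        )
        for r, f in enumerate(fractions, start=1)
    ]


def simulate_experiment(
    copy_numbers: dict,
    assays: list[SNPAssay],
    noise: AssayNoise,
    seed: int,
    *,
    ploidy: int | None = None,
    profile: ExpressionProfile | None = None,
    cdna_targets: dict | None = None,
    design: ExperimentDesign = ExperimentDesign(),
) -> pd.DataFrame:
    """Simulate a full gDNA + cDNA pyrosequencing experiment.

    ``copy_numbers`` maps allele -> genomic copies (summing to the ploidy).
    gDNA rows are centred on the copy-number null k/p.  cDNA rows are
    centred either on :func:`cdna_expected_frequency` of ``profile``
    (composition mode) or on ``cdna_targets[assay_id]`` (per-assay target
    mode); exactly one of the two must be given.

    Returns a tidy observation table (one row per replicate measurement).
    """
    if (profile is None) == (cdna_targets is None):
        raise ValueError("give exactly one of profile= or cdna_targets=")
    p = sum(copy_numbers.values()) if ploidy is None else ploidy
    if sum(copy_numbers.values()) != p:
        raise ValueError("copy numbers must sum to the ploidy")
    rng = np.random.default_rng(seed)
    rows: list[FrequencyObservation] = []
    for assay in assays:
        unknown = set(assay.carrier_alleles) - set(copy_numbers)
        if unknown:
            raise ValueError(f"assay {assay.assay_id} references unknown alleles {sorted(unknown)}")
        k = sum(copy_numbers[a] for a in assay.carrier_alleles)
        g_true = expected_frequency(k, p)
        if cdna_targets is not None:
            c_true = cdna_targets[assay.assay_id]
        else:
            c_true = cdna_expected_frequency(copy_numbers, profile, assay.carrier_alleles)
        for ind in design.individuals:
            rows += simulate_assay(
                g_true,
                noise,
                design.n_gdna_replicates,
                rng,
                assay=assay,
                template="gDNA",
                individual=ind,
            )
            for stage in design.bud_stages:
                rows += simulate_assay(
                    c_true,
                    noise,
                    design.n_cdna_replicates,
                    rng,
                    assay=assay,
                    template="cDNA",
                    individual=ind,
                    bud_stage=stage,
                )
    return observations_to_frame(rows)


def observations_to_frame(obs: list[FrequencyObservation]) -> pd.DataFrame:
    """Tidy DataFrame with the canonical observation columns."""
    return pd.DataFrame(
        [
            {
                "assay_id": o.assay_id,
                "locus": o.locus,
                "template": o.template,
                "individual": o.individual,
                "bud_stage": o.bud_stage,
                "replicate": o.replicate,
                "fraction": o.fraction,
                "depth": o.depth,
            }
            for o in obs
        ],
        columns=OBSERVATION_COLUMNS,
    )
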
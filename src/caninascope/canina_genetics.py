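"""Forward simulator of canina meiosis in dogroses.

Dogroses (*Rosa* sect. *Caninae*) are mostly pentaploid (2n = 5x = 35) yet
reproduce sexually through a unique asymmetric meiosis: only two highly
homologous chromosome sets pair as bivalents and recombine, while the
remaining sets stay as univalents.  Pollen grains carry a single recombined
bivalent-derived set (n = x = 7); egg cells carry one recombined
bivalent-derived set plus *all* univalent sets unchanged (n = 4x = 28 in
pentaploids).  Fertilization restores the somatic ploidy.

This module simulates that transmission system forward in time for
single-copy loci, tracking allele labels per chromosome set.  It supplies
genotypes with known per-allele copy numbers to the assay simulator and to
the copy-number / allele-specific-expression inference stages.

Tetraploid dogroses (haploid pollen, triploid eggs) are covered by setting
``ploidy=4``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MeiosisConfig",
    "ChromosomeSet",
    "PentaploidGenotype",
    "Gamete",
    "make_founder",
    "pollen_gamete",
    "egg_gamete",
    "fertilize",
    "evolve",
]

N_BIVALENT_SETS = 2


class ConfigurationError(ValueError):
    """Raised for invalid simulator configuration."""


class MatingError(ValueError):
    """Raised when gametes of incompatible kinds are crossed."""


@dataclass(frozen=True)
class MeiosisConfig:
    """Parameters of the canina-meiosis simulator.

    Parameters
    ----------
    base_number
        Chromosomes per monoploid set (x); 7 in *Rosa*.
    ploidy
        Chromosome sets per somatic genome; 5 for pentaploid dogroses,
        4 for tetraploids.
    recombination_rate
        Expected crossovers per chromosome per bivalent meiosis (Poisson
        mean, unitless, >= 0).  Only the two bivalent-forming sets ever
        recombine.
    mutation_rate
        Per-locus, per-transmission probability that the transmitted allele
        is replaced by a fresh, never-seen label (infinite-alleles model).
    seed
        Seed for the single random stream used by all stochastic draws.
    """

    base_number: int = 7
    ploidy: int = 5
    recombination_rate: float = 0.0
    mutation_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_number < 1:
            raise ConfigurationError("base_number must be >= 1")
        if self.ploidy < 3:
            raise ConfigurationError("ploidy must be >= 3 (2 bivalent + >=1 univalent sets)")
        if self.recombination_rate < 0 or self.mutation_rate < 0:
            raise ConfigurationError("rates must be >= 0")

    @property
    def n_bivalent_sets(self) -> int:
        return N_BIVALENT_SETS

    @property
    def n_univalent_sets(self) -> int:
        return self.ploidy - N_BIVALENT_SETS

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class ChromosomeSet:
    """One monoploid chromosome set: an allele label per (single-copy) locus.

    ``role`` is ``"bivalent"`` for the two pairing sets (labels B1, B2) and
    ``"univalent"`` for the maternally transmitted unpaired sets (U1, U2, ...).
    """

    label: str
    role: str
    alleles: tuple[tuple[str, str], ...]  # ordered (locus, allele) pairs

    def __post_init__(self) -> None:
        if self.role not in ("bivalent", "univalent"):
            raise ConfigurationError(f"unknown chromosome-set role {self.role!r}")
        expected = "bivalent" if self.label.startswith("B") else "univalent"
        if self.role != expected:
            raise ConfigurationError(f"label {self.label!r} inconsistent with role {self.role!r}")
        loci = [locus for locus, _ in self.alleles]
        if len(set(loci)) != len(loci):
            raise ConfigurationError("duplicate locus in chromosome set")

    @property
    def loci(self) -> tuple[str, ...]:
        return tuple(locus for locus, _ in self.alleles)

    def allele(self, locus: str) -> str:
        for loc, al in self.alleles:
            if loc == locus:
                return al
        raise KeyError(locus)

    def with_alleles(self, alleles: dict[str, str]) -> "ChromosomeSet":
        return replace(self, alleles=tuple((loc, alleles.get(loc, al)) for loc, al in self.alleles))


@dataclass(frozen=True)
class PentaploidGenotype:
    """A dogrose individual: 2 bivalent-role + (ploidy-2) univalent-role sets.

    Despite the name the container holds any odd or even canina ploidy;
    pentaploid is the default and the namesake case.
    """

    sets: tuple[ChromosomeSet, ...]
    individual_id: str = ""
    base_number: int = 7

    def __post_init__(self) -> None:
        n_biv = sum(1 for s in self.sets if s.role == "bivalent")
        if n_biv != N_BIVALENT_SETS:
            raise ConfigurationError(f"expected {N_BIVALENT_SETS} bivalent sets, got {n_biv}")
        if len(self.sets) < 3:
            raise ConfigurationError("need at least one univalent set")
        loci0 = self.sets[0].loci
        if any(s.loci != loci0 for s in self.sets):
            raise ConfigurationError("all chromosome sets must declare the same loci")

    @property
    def ploidy(self) -> int:
        return len(self.sets)

    @property
    def chromosome_count(self) -> int:
        """Somatic chromosome number (ploidy * x)."""
        return self.ploidy * self.base_number

    @property
    def loci(self) -> tuple[str, ...]:
        return self.sets[0].loci

    @property
    def bivalent_sets(self) -> tuple[ChromosomeSet, ...]:
        return tuple(s for s in self.sets if s.role == "bivalent")

    @property
    def univalent_sets(self) -> tuple[ChromosomeSet, ...]:
        return tuple(s for s in self.sets if s.role == "univalent")

    def copy_numbers(self, locus: str) -> dict[str, int]:
        """Per-allele copy numbers at ``locus``; values sum to the ploidy."""
        counts: dict[str, int] = {}
        for s in self.sets:
            al = s.allele(locus)
            counts[al] = counts.get(al, 0) + 1
        assert sum(counts.values()) == self.ploidy
        return counts


@dataclass(frozen=True)
class Gamete:
    """A gamete: haploid pollen (one bivalent-derived set) or an egg
    (one bivalent-derived set plus every univalent set, unrecombined)."""

    kind: str
    sets: tuple[ChromosomeSet, ...]
    base_number: int = 7

    def __post_init__(self) -> None:
        if self.kind not in ("pollen", "egg"):
            raise ConfigurationError(f"unknown gamete kind {self.kind!r}")
        if self.kind == "pollen" and len(self.sets) != 1:
            raise ConfigurationError("pollen must carry exactly one chromosome set")

    @property
    def chromosome_count(self) -> int:
        return len(self.sets) * self.base_number


def make_founder(
    bivalent_allele: str | dict[str, str],
    univalent_alleles: tuple,
    loci: list[str] | tuple[str, ...],
    individual_id: str = "founder",
    ploidy: int = 5,
    base_number: int = 7,
) -> PentaploidGenotype:
    """Build a founder with the bivalent allele duplicated on B1 and B2.

    ``bivalent_allele`` may be one label (used at every locus) or a
    locus->label mapping; each entry of ``univalent_alleles`` likewise.
    Duplicate univalent labels are allowed (they just lower the distinct
    allele count).
    """
    if not loci:
        raise ConfigurationError("at least one locus required")
    n_uni = ploidy - N_BIVALENT_SETS
    if len(univalent_alleles) != n_uni:
        raise ConfigurationError(
            f"expected {n_uni} univalent allele labels for ploidy {ploidy}, "
            f"got {len(univalent_alleles)}"
        )

    def per_locus(spec) -> tuple[tuple[str, str], ...]:
        if isinstance(spec, dict):
            return tuple((loc, spec[loc]) for loc in loci)
        return tuple((loc, spec) for loc in loci)

    sets = [
        ChromosomeSet("B1", "bivalent", per_locus(bivalent_allele)),
        ChromosomeSet("B2", "bivalent", per_locus(bivalent_allele)),
    ]
    for i, ua in enumerate(univalent_alleles, start=1):
        sets.append(ChromosomeSet(f"U{i}", "univalent", per_locus(ua)))
    return PentaploidGenotype(tuple(sets), individual_id, base_number=base_number)


def _locus_positions(loci: tuple[str, ...]) -> np.ndarray:
    # Loci are placed at evenly spaced map positions on a unit map in the
    # declared order; the map is notional (a single linkage group) since no
    # genetic map exists for these markers.
    n = len(loci)
    return (np.arange(n) + 0.5) / n


def _recombine_bivalents(
    b1: ChromosomeSet, b2: ChromosomeSet, cfg: MeiosisConfig, rng: np.random.Generator
) -> tuple[dict[str, str], dict[str, str]]:
    """One meiosis of the bivalent pair: Poisson crossovers, uniform
    breakpoints; returns the two recombination products as locus->allele."""
    loci = b1.loci
    pos = _locus_positions(loci)
    n_co = rng.poisson(cfg.recombination_rate)
    if n_co == 0:
        return dict(b1.alleles), dict(b2.alleles)
    breaks = np.sort(rng.uniform(0.0, 1.0, size=n_co))
    # phase at a position = number of breakpoints to its left, mod 2
    phase = np.searchsorted(breaks, pos) % 2
    prod1 = {
        loc: (b1.allele(loc) if ph == 0 else b2.allele(loc)) for loc, ph in zip(loci, phase)
    }
    prod2 = {
        loc: (b2.allele(loc) if ph == 0 else b1.allele(loc)) for loc, ph in zip(loci, phase)
    }
    return prod1, prod2


_MUTATION_COUNTER = itertools.count(1)


def _mutate(alleles: dict[str, str], cfg: MeiosisConfig, rng: np.random.Generator) -> dict[str, str]:
    if cfg.mutation_rate == 0:
        return alleles
    out = dict(alleles)
    for loc in out:
        if rng.random() < cfg.mutation_rate:
            out[loc] = f"novel-{next(_MUTATION_COUNTER)}"
    return out


def _bivalent_product(
    g: PentaploidGenotype, cfg: MeiosisConfig, rng: np.random.Generator, label: str
) -> ChromosomeSet:
    b1, b2 = g.bivalent_sets
    prod1, prod2 = _recombine_bivalents(b1, b2, cfg, rng)
    chosen = prod1 if rng.random() < 0.5 else prod2
    chosen = _mutate(chosen, cfg, rng)
    return ChromosomeSet(label, "bivalent", tuple((loc, chosen[loc]) for loc in b1.loci))


def pollen_gamete(
    g: PentaploidGenotype, cfg: MeiosisConfig, rng: np.random.Generator | None = None
) -> Gamete:
    """Haploid pollen: one (possibly recombined) product of the bivalent pair."""
    rng = cfg.rng() if rng is None else rng
    prod = _bivalent_product(g, cfg, rng, "B1")
    gam = Gamete("pollen", (prod,), base_number=g.base_number)
    assert gam.chromosome_count == g.base_number
    return gam


def egg_gamete(
    g: PentaploidGenotype, cfg: MeiosisConfig, rng: np.random.Generator | None = None
) -> Gamete:
    """Egg: one recombined bivalent product plus all univalent sets unchanged.

    Univalents bypass pairing entirely; with ``mutation_rate=0`` their alleles
    are transmitted bit-for-bit maternally.
    """
    rng = cfg.rng() if rng is None else rng
    prod = _bivalent_product(g, cfg, rng, "B2")
    unis = []
    for u in g.univalent_sets:
        mutated = _mutate(dict(u.alleles), cfg, rng)
        unis.append(u.with_alleles(mutated))
    gam = Gamete("egg", (prod, *unis), base_number=g.base_number)
    assert gam.chromosome_count == (g.ploidy - 1) * g.base_number
    return gam


def fertilize(pollen: Gamete, egg: Gamete, individual_id: str = "") -> PentaploidGenotype:
    """Merge a pollen and an egg gamete into a zygote.

    The pollen set and the egg's bivalent-derived set become the zygote's
    bivalent pair; the egg's univalents are carried over with relabelled
    U1..Un identities.
    """
    if pollen.kind != "pollen" or egg.kind != "egg":
        raise MatingError(f"need one pollen and one egg, got {pollen.kind} x {egg.kind}")
    b_pollen = replace(pollen.sets[0], label="B1", role="bivalent")
    egg_biv = [s for s in egg.sets if s.role == "bivalent"]
    egg_uni = [s for s in egg.sets if s.role == "univalent"]
    if len(egg_biv) != 1:
        raise MatingError("egg must carry exactly one bivalent-derived set")
    b_egg = replace(egg_biv[0], label="B2", role="bivalent")
    unis = tuple(replace(u, label=f"U{i}") for i, u in enumerate(egg_uni, start=1))
    zygote = PentaploidGenotype(
        (b_pollen, b_egg, *unis), individual_id, base_number=pollen.base_number
    )
    assert zygote.chromosome_count == zygote.ploidy * zygote.base_number
    return zygote


def evolve(
    population: list[PentaploidGenotype],
    generations: int,
    cfg: MeiosisConfig,
) -> tuple[list[PentaploidGenotype], pd.DataFrame]:
    """Random-mating forward driver over ``generations`` non-overlapping
    generations at constant population size.

    Returns the final population and a per-generation summary with, for each
    locus: the distinct-allele count distribution and the mean copy-number of
    the most frequent allele.  Seed-reproducible via ``cfg.seed``.
    """
    if not population:
        raise ConfigurationError("population must be non-empty")
    if generations < 0:
        raise ConfigurationError("generations must be >= 0")
    rng = cfg.rng()
    records = []

    def census(pop: list[PentaploidGenotype], gen: int) -> None:
        for locus in pop[0].loci:
            n_distinct = [len(p.copy_numbers(locus)) for p in pop]
            max_k = [max(p.copy_numbers(locus).values()) for p in pop]
            records.append(
                {
                    "generation": gen,
                    "locus": locus,
                    "n_individuals": len(pop),
                    "mean_distinct_alleles": float(np.mean(n_distinct)),
                    "max_distinct_alleles": int(np.max(n_distinct)),
                    "mean_max_copy_number": float(np.mean(max_k)),
                }
            )

    census(population, 0)
    pop = population
    for gen in range(1, generations + 1):
        new_pop = []
        for i in range(len(pop)):
            father = pop[rng.integers(len(pop))]
            mother = pop[rng.integers(len(pop))]
            child = fertilize(
                pollen_gamete(father, cfg, rng),
                egg_gamete(mother, cfg, rng),
                individual_id=f"g{gen}-i{i}",
            )
            new_pop.append(child)
        pop = new_pop
        census(pop, gen)
    return pop, pd.DataFrame.from_records(records)
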
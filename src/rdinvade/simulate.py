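"""Forward-time, individual-based invasion simulator.

Implements the demographic and selection model of the multigenerational
invasion assay: founder populations of 50 Rd females, 40 Rd males and
10 WT males; discrete generations in which females are paired with males
sampled with replacement, each pair produces a fixed clutch under
Mendelian inheritance, a fixed fraction of offspring survives to
adulthood, and fixed quotas of males and females are recruited into the
next breeding population.

Selection acts through a relative-fitness parameter ``alpha`` (WT vs
Rd), which can be switched on independently for three fitness
components: male reproductive success, female reproductive success
(active only after the first generation, since all founder females are
Rd) and offspring viability.  Weighted sampling uses class weights
Rd/Rd = 1, WT/WT = alpha, with heterozygotes intermediate; normalised
over the candidate pool this reproduces the 1/(alpha+1) vs
alpha/(alpha+1) sampling probabilities for an Rd/WT pair.

The module exposes both an object-level API (lists of
:class:`~rdinvade.genetics.Individual`, convenient for tests and small
examples) and a fast array core used by :func:`run_trajectory`; both
paths share the same sampling primitives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genetics import Genotype, Individual, Sex, codes_to_genotypes, genotypes_to_codes

__all__ = [
    "FitnessScheme",
    "SimulationConfig",
    "Trajectory",
    "DemographicFailureError",
    "genotype_weight",
    "make_founders",
    "form_pairs",
    "viability_select",
    "recruit",
    "step_generation",
    "run_trajectory",
]


class DemographicFailureError(RuntimeError):
    """Too few survivors of one sex to fill a recruitment quota.

    Carries the generation index at which the failure occurred.  This is
    an explicit error rather than silent truncation; at the default
    demographic parameters it is vanishingly unlikely.
    """

    def __init__(self, generation: int, message: str):
        super().__init__(f"generation {generation}: {message}")
        self.generation = generation


@dataclass(frozen=True)
class FitnessScheme:
    """Which fitness components carry the WT advantage, and how strong it is.

    Parameters
    ----------
    alpha
        Relative fitness of WT vs Rd genotypes (alpha = 2 means a
        twofold WT advantage).  ``alpha == 1`` or all effects off is the
        neutral model.
    male_effect, female_effect, offspring_effect
        Whether the advantage acts through male reproductive success,
        female reproductive success, and/or offspring viability.
    het_mode
        How heterozygote weight interpolates between the homozygote
        weights 1 and alpha: ``"arithmetic"`` (default, (1+alpha)/2) or
        ``"geometric"`` (sqrt(alpha)).
    """

    alpha: float = 1.0
    male_effect: bool = False
    female_effect: bool = False
    offspring_effect: bool = False
    het_mode: str = "arithmetic"

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.het_mode not in ("arithmetic", "geometric"):
            raise ValueError("het_mode must be 'arithmetic' or 'geometric'")

    @property
    def is_neutral(self) -> bool:
        return self.alpha == 1.0 or not (
            self.male_effect or self.female_effect or self.offspring_effect
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Demographic constants of the invasion assay design."""

    n_rd_females: int = 50
    n_rd_males: int = 40
    n_wt_males: int = 10
    offspring_per_pair: int = 52
    survival_fraction: float = 0.30
    recruit_males: int = 230
    recruit_females: int = 230
    n_generations: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_rd_females",
            "n_rd_males",
            "n_wt_males",
            "offspring_per_pair",
            "recruit_males",
            "recruit_females",
            "n_generations",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.survival_fraction <= 1:
            raise ValueError("survival_fraction must be in (0, 1]")


@dataclass
class Trajectory:
    """Per-generation adult genotype composition of one replicate.

    Generation 0 is the founder population; generations 1..n are the
    recruited breeding adults.  ``prop_wt_homozygote`` is the quantity
    tracked by the invasion assay, since WT phenotype == WT homozygote
    under Rd dominance.
    """

    n_wt_hom: np.ndarray  # adults with 2 WT alleles, per generation
    n_het: np.ndarray
    n_rd_hom: np.ndarray

    @property
    def n_generations(self) -> int:
        return len(self.n_wt_hom) - 1

    @property
    def n_adults(self) -> np.ndarray:
        return self.n_wt_hom + self.n_het + self.n_rd_hom

    @property
    def prop_wt_homozygote(self) -> np.ndarray:
        return self.n_wt_hom / self.n_adults

    @property
    def wt_allele_frequency(self) -> np.ndarray:
        return (2 * self.n_wt_hom + self.n_het) / (2 * self.n_adults)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": np.arange(len(self.n_wt_hom)),
                "n_wt_hom": self.n_wt_hom,
                "n_het": self.n_het,
                "n_rd_hom": self.n_rd_hom,
                "prop_wt_homozygote": self.prop_wt_homozygote,
            }
        )


# ---------------------------------------------------------------------------
# Sampling primitives (shared by the list API and the array core)
# ---------------------------------------------------------------------------

def genotype_weight(genotype: Genotype | int, alpha: float, het_mode: str = "arithmetic") -> float:
    """Unnormalised selection weight of a genotype class.

    Rd/Rd -> 1, WT/WT -> alpha, heterozygote -> intermediate.
    Normalisation happens at sampling time over the candidate pool, so a
    pool of one Rd/Rd and one WT/WT is sampled with probabilities
    1/(alpha+1) and alpha/(alpha+1).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    n_wt = genotype if isinstance(genotype, (int, np.integer)) else genotype.n_wt
    return float(_class_weights(alpha, het_mode)[n_wt])


def _class_weights(alpha: float, het_mode: str) -> np.ndarray:
    """Weights indexed by WT-allele count (0, 1, 2)."""
    het = (1.0 + alpha) / 2.0 if het_mode == "arithmetic" else math.sqrt(alpha)
    return np.array([1.0, het, alpha])


def _sample_with_replacement(
    codes: np.ndarray,
    k: int,
    weighted: bool,
    alpha: float,
    het_mode: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Indices of ``k`` draws with replacement, genotype-weighted or uniform."""
    n = len(codes)
    if weighted:
        w = _class_weights(alpha, het_mode)[codes]
        p = w / w.sum()
        return rng.choice(n, size=k, replace=True, p=p)
    return rng.integers(0, n, size=k)


def _sample_without_replacement(
    codes: np.ndarray,
    k: int,
    weighted: bool,
    alpha: float,
    het_mode: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Indices of ``k`` draws without replacement.

    The weighted case uses exponential sort keys (key = Exp(1)/weight,
    keep the k smallest), equivalent to successive draws with weight
    renormalisation.  With equal weights this reduces to a uniform
    subsample, so toggling the effect changes only the weights, never
    the sampling mechanism.
    """
    n = len(codes)
    if k > n:
        raise ValueError("cannot sample more items than the pool holds")
    w = _class_weights(alpha, het_mode)[codes] if weighted else np.ones(n)
    keys = rng.standard_exponential(n) / w
    if k == n:
        return np.arange(n)
    return np.argpartition(keys, k)[:k]


def _cross_codes(
    mother_codes: np.ndarray,
    father_codes: np.ndarray,
    n_per_pair: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised Mendelian transmission for paired parents.

    Each parent transmits a WT allele with probability n_wt/2; the
    offspring code is the sum of the two transmitted-alle indicator
    draws.
    """
    pm = np.repeat(mother_codes, n_per_pair) / 2.0
    pf = np.repeat(father_codes, n_per_pair) / 2.0
    n = len(pm)
    maternal = rng.random(n) < pm
    paternal = rng.random(n) < pf
    return (maternal.astype(np.int8) + paternal.astype(np.int8))


# ---------------------------------------------------------------------------
# Object-level operations
# ---------------------------------------------------------------------------

def make_founders(config: SimulationConfig) -> list[Individual]:
    """Founder population: Rd/Rd females and males plus WT/WT male colonists."""
    rd = Genotype.from_n_wt(0)
    wt = Genotype.from_n_wt(2)
    founders = [Individual(Sex.FEMALE, rd) for _ in range(config.n_rd_females)]
    founders += [Individual(Sex.MALE, rd) for _ in range(config.n_rd_males)]
    founders += [Individual(Sex.MALE, wt) for _ in range(config.n_wt_males)]
    return founders


def form_pairs(
    females: Sequence[Individual],
    males: Sequence[Individual],
    scheme: FitnessScheme,
    generation_index: int,
    rng: np.random.Generator,
) -> list[tuple[Individual, Individual]]:
    """Form one mating pair per female slot.

    Both sexes are sampled with replacement; males are genotype-weighted
    iff ``male_effect`` is on, females iff ``female_effect`` is on and
    the parental generation index is >= 1 (the female advantage only
    comes into effect after the first generation).
    """
    if len(females) == 0 or len(males) == 0:
        raise DemographicFailureError(generation_index, "empty parental sex pool")
    f_codes = genotypes_to_codes(ind.genotype for ind in females)
    m_codes = genotypes_to_codes(ind.genotype for ind in males)
    n_pairs = len(females)
    female_weighted = scheme.female_effect and generation_index >= 1
    fi = _sample_with_replacement(
        f_codes, n_pairs, female_weighted, scheme.alpha, scheme.het_mode, rng
    )
    mi = _sample_with_replacement(
        m_codes, n_pairs, scheme.male_effect, scheme.alpha, scheme.het_mode, rng
    )
    return [(females[i], males[j]) for i, j in zip(fi, mi)]


def viability_select(
    offspring: Sequence[Genotype],
    scheme: FitnessScheme,
    survival_fraction: float,
    rng: np.random.Generator,
) -> list[Genotype]:
    """Keep floor(survival_fraction * n) offspring, without replacement.

    Survivors are genotype-weighted iff ``offspring_effect`` is on,
    otherwise a uniform thinning.
    """
    if len(offspring) == 0:
        raise DemographicFailureError(-1, "no offspring to select from")
    if not 0 < survival_fraction <= 1:
        raise ValueError("survival_fraction must be in (0, 1]")
    codes = genotypes_to_codes(offspring)
    k = int(survival_fraction * len(offspring))
    idx = _sample_without_replacement(
        codes, k, scheme.offspring_effect, scheme.alpha, scheme.het_mode, rng
    )
    return [offspring[i] for i in idx]


def recruit(
    survivors: Sequence[Genotype],
    recruit_males: int,
    recruit_females: int,
    rng: np.random.Generator,
    generation_index: int = -1,
) -> list[Individual]:
    """Assign sexes by fair coin and fill both recruitment quotas.

    Raises :class:`DemographicFailureError` if either sex cannot fill
    its quota.
    """
    codes = genotypes_to_codes(survivors)
    g_f, g_m = _recruit_codes(codes, recruit_males, recruit_females, rng, generation_index)
    out = [Individual(Sex.FEMALE, g) for g in codes_to_genotypes(g_f)]
    out += [Individual(Sex.MALE, g) for g in codes_to_genotypes(g_m)]
    return out


def _recruit_codes(
    survivor_codes: np.ndarray,
    recruit_males: int,
    recruit_females: int,
    rng: np.random.Generator,
    generation_index: int,
) -> tuple[np.ndarray, np.ndarray]:
    is_female = rng.random(len(survivor_codes)) < 0.5
    females = survivor_codes[is_female]
    males = survivor_codes[~is_female]
    if len(females) < recruit_females or len(males) < recruit_males:
        raise DemographicFailureError(
            generation_index,
            f"survivors provide {len(females)} females / {len(males)} males "
            f"for quotas {recruit_females}/{recruit_males}",
        )
    g_f = females[rng.permutation(len(females))[:recruit_females]]
    g_m = males[rng.permutation(len(males))[:recruit_males]]
    return g_f, g_m


def step_generation(
    adults: Sequence[Individual],
    scheme: FitnessScheme,
    config: SimulationConfig,
    generation_index: int,
    rng: np.random.Generator,
) -> list[Individual]:
    """One full generation: pair, reproduce, select, recruit."""
    f_codes = genotypes_to_codes(a.genotype for a in adults if a.sex is Sex.FEMALE)
    m_codes = genotypes_to_codes(a.genotype for a in adults if a.sex is Sex.MALE)
    g_f, g_m = _step_codes(f_codes, m_codes, scheme, config, generation_index, rng)
    out = [Individual(Sex.FEMALE, g) for g in codes_to_genotypes(g_f)]
    out += [Individual(Sex.MALE, g) for g in codes_to_genotypes(g_m)]
    return out


def _step_codes(
    f_codes: np.ndarray,
    m_codes: np.ndarray,
    scheme: FitnessScheme,
    config: SimulationConfig,
    generation_index: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Array core of one generation step; returns next (females, males).

    The number of mating slots per generation is the female recruitment
    quota (a constant of the breeding design), with mothers sampled with
    replacement — founder females therefore fill the same number of
    slots as recruited females do in later generations.  This keeps the
    per-generation offspring pool constant, which is what makes the
    low-survival (10%) sensitivity runs demographically feasible.
    """
    if len(f_codes) == 0 or len(m_codes) == 0:
        raise DemographicFailureError(generation_index, "empty parental sex pool")
    n_pairs = config.recruit_females
    female_weighted = scheme.female_effect and generation_index >= 1
    fi = _sample_with_replacement(
        f_codes, n_pairs, female_weighted, scheme.alpha, scheme.het_mode, rng
    )
    mi = _sample_with_replacement(
        m_codes, n_pairs, scheme.male_effect, scheme.alpha, scheme.het_mode, rng
    )
    offspring = _cross_codes(f_codes[fi], m_codes[mi], config.offspring_per_pair, rng)
    k = int(config.survival_fraction * len(offspring))
    surv_idx = _sample_without_replacement(
        offspring, k, scheme.offspring_effect, scheme.alpha, scheme.het_mode, rng
    )
    survivors = offspring[surv_idx]
    return _recruit_codes(
        survivors, config.recruit_males, config.recruit_females, rng, generation_index + 1
    )


def run_trajectory(
    scheme: FitnessScheme,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> Trajectory:
    """Run one replicate for ``config.n_generations`` generations.

    Records the adult genotype composition at every generation,
    including the founder generation 0.
    """
    f_codes = np.zeros(config.n_rd_females, dtype=np.int8)
    m_codes = np.concatenate(
        [
            np.zeros(config.n_rd_males, dtype=np.int8),
            np.full(config.n_wt_males, 2, dtype=np.int8),
        ]
    )
    n_gen = config.n_generations
    n_wt_hom = np.zeros(n_gen + 1, dtype=np.int64)
    n_het = np.zeros(n_gen + 1, dtype=np.int64)
    n_rd_hom = np.zeros(n_gen + 1, dtype=np.int64)

    def record(t: int) -> None:
        codes = np.concatenate([f_codes, m_codes])
        n_wt_hom[t] = int((codes == 2).sum())
        n_het[t] = int((codes == 1).sum())
        n_rd_hom[t] = int((codes == 0).sum())

    record(0)
    for t in range(n_gen):
        f_codes, m_codes = _step_codes(f_codes, m_codes, scheme, config, t, rng)
        record(t + 1)
    return Trajectory(n_wt_hom=n_wt_hom, n_het=n_het, n_rd_hom=n_rd_hom)
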
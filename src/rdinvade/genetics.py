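"""Single-locus Mendelian genetics for the dominant Reindeer (Rd) marker.

The whole system is described by one autosomal locus with two alleles:
the wild-type allele ``WT`` and the dominant marker allele ``Rd``.
Heterozygotes display the Rd phenotype (swollen antennae), so the WT
phenotype is only expressed by WT/WT homozygotes.  Internally a genotype
is summarised by its number of WT alleles (0, 1 or 2), which is also the
array encoding used by the vectorised simulation engine.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Allele",
    "Sex",
    "Phenotype",
    "Genotype",
    "Individual",
    "phenotype_of",
    "mendelian_cross",
    "allele_frequency",
]


class Allele(enum.Enum):
    """The two allele states at the marker locus."""

    WT = "WT"
    Rd = "Rd"


class Sex(enum.Enum):
    FEMALE = "female"
    MALE = "male"


class Phenotype(enum.Enum):
    """Visible antennal phenotype; Rd is dominant."""

    WT = "WT_phenotype"
    Rd = "Rd_phenotype"


@dataclass(frozen=True, slots=True)
class Genotype:
    """Ordered (maternal, paternal) allele pair.

    The ordering preserves transmission information for tests; equality
    and phenotype are evaluated unordered, so there are three genotype
    classes: WT/WT, WT/Rd and Rd/Rd.
    """

    allele_maternal: Allele
    allele_paternal: Allele

    @property
    def n_wt(self) -> int:
        """Number of WT alleles carried (0, 1 or 2)."""
        return int(self.allele_maternal is Allele.WT) + int(
            self.allele_paternal is Allele.WT
        )

    def same_class(self, other: "Genotype") -> bool:
        """Unordered genotype-class comparison."""
        return self.n_wt == other.n_wt

    @classmethod
    def from_n_wt(cls, n_wt: int) -> "Genotype":
        if n_wt == 0:
            return cls(Allele.Rd, Allele.Rd)
        if n_wt == 1:
            return cls(Allele.WT, Allele.Rd)
        if n_wt == 2:
            return cls(Allele.WT, Allele.WT)
        raise ValueError(f"n_wt must be 0, 1 or 2, got {n_wt}")


# Canonical genotypes, handy in tests.
RD_HOM = Genotype(Allele.Rd, Allele.Rd)
HET = Genotype(Allele.WT, Allele.Rd)
WT_HOM = Genotype(Allele.WT, Allele.WT)


@dataclass(frozen=True, slots=True)
class Individual:
    """A beetle: sex plus diploid genotype at the marker locus."""

    sex: Sex
    genotype: Genotype


def phenotype_of(genotype: Genotype) -> Phenotype:
    """Score the visible phenotype under Rd dominance.

    WT phenotype requires WT/WT homozygosity; heterozygotes are scored
    as the Rd phenotype.
    """
    return Phenotype.WT if genotype.n_wt == 2 else Phenotype.Rd


def mendelian_cross(
    mother: Individual,
    father: Individual,
    n_offspring: int,
    rng: np.random.Generator,
) -> list[Genotype]:
    """Simulate offspring genotypes for one mating pair.

    Each offspring independently receives one allele sampled uniformly
    from each parent.

    Parameters
    ----------
    mother, father
        Parents; ``mother`` must be female and ``father`` male.
    n_offspring
        Number of offspring to draw (>= 0).
    rng
        Explicit random source; no global state is touched.
    """
    if mother.sex is not Sex.FEMALE:
        raise ValueError("mother must be female")
    if father.sex is not Sex.MALE:
        raise ValueError("father must be male")
    if n_offspring < 0:
        raise ValueError("n_offspring must be non-negative")
    if n_offspring == 0:
        return []
    gm, gf = mother.genotype, father.genotype
    maternal = rng.random(n_offspring) < 0.5
    paternal = rng.random(n_offspring) < 0.5
    out = []
    for pick_m, pick_p in zip(maternal, paternal):
        a_m = gm.allele_maternal if pick_m else gm.allele_paternal
        a_p = gf.allele_maternal if pick_p else gf.allele_paternal
        out.append(Genotype(a_m, a_p))
    return out


def allele_frequency(individuals: Sequence[Individual], allele: Allele) -> float:
    """Frequency of ``allele`` among the 2N allele copies carried."""
    if len(individuals) == 0:
        raise ValueError("allele_frequency of an empty population is undefined")
    count = sum(
        (ind.genotype.allele_maternal is allele)
        + (ind.genotype.allele_paternal is allele)
        for ind in individuals
    )
    return count / (2 * len(individuals))


# ---------------------------------------------------------------------------
# Array bridge used by the vectorised simulator: genotype code = n_wt alleles.
# ---------------------------------------------------------------------------

def genotypes_to_codes(genotypes: Iterable[Genotype]) -> np.ndarray:
    return np.fromiter((g.n_wt for g in genotypes), dtype=np.int8)


def codes_to_genotypes(codes: np.ndarray) -> list[Genotype]:
    return [Genotype.from_n_wt(int(c)) for c in codes]
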
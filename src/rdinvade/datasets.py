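"""Synthetic datasets with the statistical structure of the two empirical assays.

Two generators are provided:

* :func:`generate_invasion_dataset` emulates the 24-population invasion
  experiment (2 sexual-selection regimes x 3 lines x 4 replicate
  populations).  Each population is a forward simulation under its
  regime's fitness scheme; at each of generations 2-8 a bounded random
  subsample of adults is scored by dominance (heterozygotes counted as
  the Rd phenotype), yielding per-population phenotype counts.

* :func:`generate_fecundity_dataset` emulates the five noncompetitive
  fecundity crosses (Rd x Rd pairs; within-regime WT pairs; WT male x
  Rd female; hybrid son x Rd female; Rd male x hybrid daughter) as
  overdispersed negative-binomial offspring counts with group-specific
  means.

Both datasets are plain tidy DataFrames, fully determined by their
parameters and a seed, and round-trip through CSV.  A packaged fixture
(``table1.csv``) carries the published per-generation regime means and
SEs of the real invasion assay for use by the analysis module.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .scenarios import scheme_for
from .simulate import FitnessScheme, SimulationConfig, run_trajectory

__all__ = [
    "REGIMES",
    "LINES",
    "CROSS_TYPES",
    "GeneratorParams",
    "DatasetFormatError",
    "generate_invasion_dataset",
    "generate_fecundity_dataset",
    "write_dataset",
    "read_dataset",
    "load_table1",
    "table1_as_dataset",
]

REGIMES = ("Monogamy", "Polyandry")
LINES = ("A", "B", "C")
CROSS_TYPES = (
    "RdxRd",
    "SSxSS",
    "SSmale_x_RdFemale",
    "HybridSon_x_RdFemale",
    "RdMale_x_HybridDaughter",
)

INVASION_COLUMNS = [
    "regime",
    "line",
    "replicate",
    "generation",
    "n_wt_phenotype",
    "n_rd_phenotype",
]
FECUNDITY_COLUMNS = ["cross_type", "regime", "line", "offspring_count"]

# Pair counts per line x regime for the inter-strain crosses (c)-(e);
# totals 139, 138 and 138 with 21-24 pairs per cell, matching the
# published design.  Order: (Monogamy A,B,C, Polyandry A,B,C).
_CROSS_GROUP_SIZES = {
    "SSmale_x_RdFemale": (24, 23, 23, 23, 23, 23),
    "HybridSon_x_RdFemale": (23, 23, 23, 23, 23, 23),
    "RdMale_x_HybridDaughter": (23, 23, 23, 23, 23, 23),
}


class DatasetFormatError(ValueError):
    """A dataset file does not conform to the expected tidy schema."""


@dataclass(frozen=True)
class GeneratorParams:
    """Defaults for both synthetic generators.

    The generative fitness schemes encode the scenario most consistent
    with the observed invasion data: all three fitness components
    active, with a stronger WT advantage for the Polyandry background
    (alpha = 2) than for Monogamy (alpha = 1.5).  These are generator
    defaults for producing realistic-looking data, not inferences about
    real beetles.

    Subsample sizes follow a truncated normal with the empirical mean
    (461) and range (167-586); only the mean and range are published,
    so the spread (sd = 70) is a modelling choice.

    Fecundity counts are negative binomial.  ``fecundity_dispersion``
    is the NB size parameter k (variance = mu + mu^2/k); the default
    k = 110 gives a group SE of ~2 at the Rd x Rd mean of 96 with 45
    pairs, matching the published 96 +/- 2.  ``inf`` gives the Poisson
    limit.
    """

    polyandry_scheme: FitnessScheme = field(
        default_factory=lambda: scheme_for("viii", alpha=2.0)
    )
    monogamy_scheme: FitnessScheme = field(
        default_factory=lambda: scheme_for("viii", alpha=1.5)
    )
    subsample_mean: float = 461.0
    subsample_sd: float = 70.0
    subsample_min: int = 167
    subsample_max: int = 586
    # mean offspring per pair by cross type; crosses with an Rd dam use
    # the Rd intra-strain mean, the hybrid-daughter cross the midpoint
    fecundity_means: dict = field(
        default_factory=lambda: {
            "RdxRd": 96.0,
            "SSxSS": 76.0,
            "SSmale_x_RdFemale": 96.0,
            "HybridSon_x_RdFemale": 96.0,
            "RdMale_x_HybridDaughter": 86.0,
        }
    )
    fecundity_dispersion: float = 110.0
    n_rd_pairs: int = 45
    n_ss_pairs_per_line: int = 9
    # optional line-level heterogeneity: per-line multiplicative jitter
    # on alpha (lognormal sd on the log scale); 0 disables it
    line_alpha_sd: float = 0.0

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.fecundity_means.values()):
            raise ValueError("fecundity means must be positive")
        if self.fecundity_dispersion <= 0:
            raise ValueError("fecundity dispersion must be positive")
        if not self.subsample_min <= self.subsample_mean <= self.subsample_max:
            raise ValueError("subsample mean must lie inside its bounds")


def scheme_for_regime(params: GeneratorParams, regime: str) -> FitnessScheme:
    if regime == "Polyandry":
        return params.polyandry_scheme
    if regime == "Monogamy":
        return params.monogamy_scheme
    raise ValueError(f"unknown regime {regime!r}")


def _draw_subsample_size(params: GeneratorParams, rng: np.random.Generator) -> int:
    lo = (params.subsample_min - params.subsample_mean) / params.subsample_sd
    hi = (params.subsample_max - params.subsample_mean) / params.subsample_sd
    x = stats.truncnorm.rvs(
        lo, hi, loc=params.subsample_mean, scale=params.subsample_sd, random_state=rng
    )
    return int(np.clip(round(x), params.subsample_min, params.subsample_max))


def generate_invasion_dataset(
    params: GeneratorParams,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Synthetic 24-population invasion dataset (generations 2-8).

    For each population one trajectory is simulated under the regime's
    fitness scheme.  Scoring starts at generation 2: WT colonists are
    male-only, so all first-generation offspring of WT sires are
    heterozygous and invisible under Rd dominance.  Scored counts are
    binomial draws of the subsample size against the population's
    WT-homozygote proportion, reflecting that the experimenters score a
    mixed subsample of a larger adult pool by phenotype only.
    """
    config = config or SimulationConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    records = []
    for regime in REGIMES:
        base = scheme_for_regime(params, regime)
        for line in LINES:
            scheme = base
            if params.line_alpha_sd > 0:
                jitter = math.exp(rng.normal(0.0, params.line_alpha_sd))
                from dataclasses import replace

                scheme = replace(base, alpha=max(base.alpha * jitter, 1e-6))
            for replicate in range(1, 5):
                traj = run_trajectory(scheme, config, rng)
                props = traj.prop_wt_homozygote
                for generation in range(2, config.n_generations + 1):
                    n_total = _draw_subsample_size(params, rng)
                    n_wt = int(rng.binomial(n_total, props[generation]))
                    records.append(
                        (regime, line, replicate, generation, n_wt, n_total - n_wt)
                    )
    return pd.DataFrame(records, columns=INVASION_COLUMNS)


def _nb_draw(
    mean: float, dispersion: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    if not math.isfinite(dispersion):
        return rng.poisson(mean, size=size)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def generate_fecundity_dataset(
    params: GeneratorParams | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Synthetic noncompetitive fecundity dataset for the five cross types.

    Group sizes follow the published design: 45 Rd x Rd pairs; 9 WT
    pairs per line per regime (27 per regime); 21-24 pairs per line per
    regime for the three inter-strain crosses.  Counts are negative
    binomial with group-specific means.  Fields that do not apply to a
    cross (regime/line of pure-Rd pairs) are empty strings.
    """
    params = params or GeneratorParams()
    rng = rng if rng is not None else np.random.default_rng(0)
    records = []

    counts = _nb_draw(
        params.fecundity_means["RdxRd"], params.fecundity_dispersion, params.n_rd_pairs, rng
    )
    records += [("RdxRd", "", "", int(c)) for c in counts]

    for regime in REGIMES:
        for line in LINES:
            counts = _nb_draw(
                params.fecundity_means["SSxSS"],
                params.fecundity_dispersion,
                params.n_ss_pairs_per_line,
                rng,
            )
            records += [("SSxSS", regime, line, int(c)) for c in counts]

    for cross, sizes in _CROSS_GROUP_SIZES.items():
        for (regime, line), n in zip(
            [(r, l) for r in REGIMES for l in LINES], sizes
        ):
            counts = _nb_draw(
                params.fecundity_means[cross], params.fecundity_dispersion, n, rng
            )
            records += [(cross, regime, line, int(c)) for c in counts]

    return pd.DataFrame(records, columns=FECUNDITY_COLUMNS)


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------

def write_dataset(path: str | Path, dataset: pd.DataFrame) -> None:
    """Write a tidy dataset CSV with header."""
    dataset.to_csv(path, index=False)


def read_dataset(path: str | Path, kind: str = "invasion") -> pd.DataFrame:
    """Read and validate a dataset CSV written by :func:`write_dataset`.

    ``kind`` selects the expected schema (``"invasion"`` or
    ``"fecundity"``).  Missing columns, non-integer counts or negative
    counts raise :class:`DatasetFormatError`.
    """
    if kind == "invasion":
        columns, count_cols = INVASION_COLUMNS, ["n_wt_phenotype", "n_rd_phenotype"]
        int_cols = ["replicate", "generation", *count_cols]
    elif kind == "fecundity":
        columns, count_cols = FECUNDITY_COLUMNS, ["offspring_count"]
        int_cols = count_cols
    else:
        raise ValueError(f"unknown dataset kind {kind!r}")
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    missing = set(columns) - set(df.columns)
    if missing:
        raise DatasetFormatError(f"missing columns: {sorted(missing)}")
    for col in int_cols:
        values = pd.to_numeric(df[col], errors="coerce")
        if values.isna().any():
            raise DatasetFormatError(f"non-numeric values in column {col!r}")
        if not np.allclose(values, np.round(values)):
            raise DatasetFormatError(f"non-integer values in column {col!r}")
        df[col] = values.astype(int)
    for col in count_cols:
        if (df[col] < 0).any():
            raise DatasetFormatError(f"negative counts in column {col!r}")
    for col in columns:
        if col not in int_cols:
            df[col] = df[col].astype(str)
    return df[columns]


# ---------------------------------------------------------------------------
# Packaged empirical reference fixture
# ---------------------------------------------------------------------------

def load_table1() -> pd.DataFrame:
    """Published regime means and SEs of the real invasion assay.

    Columns: generation, monogamy_mean, monogamy_se, polyandry_mean,
    polyandry_se; generations 2-8.
    """
    ref = importlib.resources.files("rdinvade").joinpath("data/table1.csv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, comment="#")


def table1_as_dataset(n_adults: int = 200) -> pd.DataFrame:
    """Expand the reference means into a count dataset.

    Each regime x generation mean is replicated as 12 identical
    populations of ``n_adults`` scored adults, giving a dataset whose
    regime summary reproduces the printed means exactly.  ``n_adults``
    must make every printed two-decimal proportion an integer count
    (any multiple of 100, or 200 by default, does).
    """
    t1 = load_table1()
    records = []
    for _, row in t1.iterrows():
        for regime, mean_col in (("Monogamy", "monogamy_mean"), ("Polyandry", "polyandry_mean")):
            n_wt = row[mean_col] * n_adults
            if abs(n_wt - round(n_wt)) > 1e-9:
                raise ValueError(
                    f"n_adults={n_adults} does not yield integer counts for mean {row[mean_col]}"
                )
            n_wt = int(round(n_wt))
            for line in LINES:
                for replicate in range(1, 5):
                    records.append(
                        (regime, line, replicate, int(row["generation"]), n_wt, n_adults - n_wt)
                    )
    return pd.DataFrame(records, columns=INVASION_COLUMNS)
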
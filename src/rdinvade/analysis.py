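"""Introgression summaries, regime contrasts and scenario-fit scoring.

The observed quantity throughout is the proportion of adults showing
the WT phenotype, which under Rd dominance equals the proportion of
WT/WT homozygotes — the same quantity the simulator tracks, so observed
trajectories and simulated ones are directly comparable.

Three analysis surfaces:

* :func:`regime_summary` / :func:`regime_difference` — per-regime,
  per-generation means and SEs across the 12 populations of each
  regime, and the Polyandry-minus-Monogamy difference trajectory.
* :func:`permutation_regime_test` — a distribution-free test of the
  regime contrast that permutes population regime labels within line,
  respecting the hierarchical design.  This is the in-package
  inferential surface (mixed-model fits on the raw replicate data are
  out of scope).
* :func:`scenario_fit` — scores every simulated (scenario, alpha) cell
  against an observed regime trajectory by RMSE over generations 2-8
  and ranks the cells, turning the visual "which simulation matches the
  data" comparison into an explicit model selection.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import LINES, REGIMES
from .scenarios import TrajectorySummary

__all__ = [
    "DataError",
    "proportion_wt",
    "regime_summary",
    "regime_difference",
    "PermutationResult",
    "permutation_regime_test",
    "scenario_fit",
]

GENERATIONS = tuple(range(2, 9))


class DataError(ValueError):
    """Input data do not cover the required regimes/generations."""


def proportion_wt(n_wt: int, n_rd: int) -> float:
    """Proportion of scored adults showing the WT phenotype."""
    total = n_wt + n_rd
    if total <= 0:
        raise ValueError("total count must be positive")
    return n_wt / total


def _population_proportions(dataset: pd.DataFrame) -> pd.DataFrame:
    df = dataset.copy()
    totals = df["n_wt_phenotype"] + df["n_rd_phenotype"]
    if (totals <= 0).any():
        raise DataError("every record needs a positive total count")
    df["proportion_wt"] = df["n_wt_phenotype"] / totals
    return df


def regime_summary(dataset: pd.DataFrame) -> pd.DataFrame:
    """Mean and SE of population WT-phenotype proportions.

    Returns a frame indexed by (regime, generation) with columns
    ``mean``, ``se`` and ``n_populations``; requires both regimes and
    every generation 2-8 to be present.
    """
    df = _population_proportions(dataset)
    out = (
        df.groupby(["regime", "generation"])["proportion_wt"]
        .agg(mean="mean", se=lambda x: x.std(ddof=1) / np.sqrt(len(x)), n_populations="size")
        .sort_index()
    )
    out["se"] = out["se"].fillna(0.0)  # single-population cells
    expected = {(r, g) for r in REGIMES for g in GENERATIONS}
    missing = expected - set(out.index)
    if missing:
        raise DataError(f"missing regime x generation cells: {sorted(missing)}")
    return out


def regime_difference(summary: pd.DataFrame) -> tuple[pd.Series, int]:
    """Polyandry-minus-Monogamy mean difference per generation.

    Returns the per-generation difference and the generation at which
    it is largest.
    """
    poly = summary.loc["Polyandry"]["mean"]
    mono = summary.loc["Monogamy"]["mean"]
    diff = (poly - mono).rename("difference")
    return diff, int(diff.idxmax())


@dataclass
class PermutationResult:
    statistic: float
    pvalue: float
    n_permutations: int
    exact: bool

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        kind = "exact" if self.exact else "Monte Carlo"
        return (
            f"PermutationResult(statistic={self.statistic:.4f}, "
            f"pvalue={self.pvalue:.4g}, {kind}, n={self.n_permutations})"
        )


def _regime_stat(values: np.ndarray, is_poly: np.ndarray) -> float:
    """Mean population-level proportion difference, Polyandry - Monogamy."""
    return float(values[is_poly].mean() - values[~is_poly].mean())


def permutation_regime_test(
    dataset: pd.DataFrame,
    n_permutations: int = 10_000,
    rng: np.random.Generator | None = None,
) -> PermutationResult:
    """Within-line permutation test of the regime contrast.

    The statistic is the difference (Polyandry - Monogamy) of the
    regime means of per-population proportions averaged over
    generations; regime labels are permuted across populations within
    each line, preserving the nested design.  Enumerates all label
    arrangements when their number does not exceed ``n_permutations``,
    otherwise uses Monte Carlo with an add-one p-value.
    """
    if n_permutations < 100:
        warnings.warn(
            "fewer than 100 permutations gives a very coarse p-value",
            UserWarning,
            stacklevel=2,
        )
    rng = rng if rng is not None else np.random.default_rng(0)
    df = _population_proportions(dataset)
    pop = (
        df.groupby(["line", "regime", "replicate"])["proportion_wt"]
        .mean()
        .reset_index()
    )
    for regime in REGIMES:
        if (pop["regime"] == regime).sum() < 2:
            raise DataError(f"need at least 2 populations in regime {regime!r}")

    lines = [str(l) for l in pd.unique(pop["line"])]
    values_by_line = []
    poly_counts = []
    for line in lines:
        sub = pop[pop["line"] == line]
        values_by_line.append(sub["proportion_wt"].to_numpy())
        poly_counts.append(int((sub["regime"] == "Polyandry").sum()))
    observed_mask = np.concatenate(
        [
            (pop[pop["line"] == line]["regime"] == "Polyandry").to_numpy()
            for line in lines
        ]
    )
    values = np.concatenate(values_by_line)
    t_obs = _regime_stat(values, observed_mask)

    # number of distinct within-line label arrangements
    from math import comb

    total = 1
    for vals, k in zip(values_by_line, poly_counts):
        total *= comb(len(vals), k)

    if total <= n_permutations:
        # exact: enumerate every arrangement (identity included)
        per_line_masks = []
        for vals, k in zip(values_by_line, poly_counts):
            masks = []
            for idx in itertools.combinations(range(len(vals)), k):
                m = np.zeros(len(vals), dtype=bool)
                m[list(idx)] = True
                masks.append(m)
            per_line_masks.append(masks)
        count = 0
        for combo in itertools.product(*per_line_masks):
            mask = np.concatenate(combo)
            if abs(_regime_stat(values, mask)) >= abs(t_obs) - 1e-12:
                count += 1
        return PermutationResult(t_obs, count / total, total, exact=True)

    # Monte Carlo: draw all within-line label shuffles at once
    n_poly = int(observed_mask.sum())
    n_mono = len(values) - n_poly
    total_sum = values.sum()
    poly_sums = np.zeros(n_permutations)
    for vals, k in zip(values_by_line, poly_counts):
        order = np.argsort(rng.random((n_permutations, len(vals))), axis=1)
        poly_sums += vals[order[:, :k]].sum(axis=1)
    t_perm = poly_sums / n_poly - (total_sum - poly_sums) / n_mono
    count = int((np.abs(t_perm) >= abs(t_obs) - 1e-12).sum())
    pvalue = (1 + count) / (n_permutations + 1)
    return PermutationResult(t_obs, pvalue, n_permutations, exact=False)


def scenario_fit(
    observed: pd.DataFrame,
    summaries: Sequence[TrajectorySummary],
    regime: str,
    metric: str = "rmse",
) -> pd.DataFrame:
    """Rank simulated cells by distance to an observed regime trajectory.

    ``observed`` is a :func:`regime_summary` frame; the distance is the
    RMSE (or MAE with ``metric="mae"``) between each cell's median
    trajectory and the observed means over generations 2-8.  Returns a
    frame sorted by ascending distance with a ``rank`` column (1 =
    best fit).
    """
    if metric not in ("rmse", "mae"):
        raise ValueError("metric must be 'rmse' or 'mae'")
    if regime not in observed.index.get_level_values("regime"):
        raise DataError(f"regime {regime!r} not present in observed summary")
    obs = observed.loc[regime]["mean"].reindex(list(GENERATIONS))
    if obs.isna().any():
        raise DataError("observed summary must cover generations 2-8")
    obs_values = obs.to_numpy()

    rows = []
    for s in summaries:
        if len(s.median) <= GENERATIONS[-1]:
            raise DataError(
                f"summary cell {s.scenario}/alpha={s.alpha} does not cover generation 8"
            )
        sim = s.median[list(GENERATIONS)]
        err = sim - obs_values
        dist = (
            float(np.sqrt(np.mean(err**2))) if metric == "rmse" else float(np.mean(np.abs(err)))
        )
        rows.append(
            {
                "scenario": s.scenario,
                "alpha": s.alpha,
                "survival_fraction": s.survival_fraction,
                "distance": dist,
            }
        )
    out = pd.DataFrame(rows)
    out = out.sort_values(
        ["distance", "scenario", "alpha"], kind="stable", ignore_index=True
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out
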
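"""Model/Results interface tying the pipeline together.

:class:`InvasionModel` wraps an observed (or synthetic) invasion
dataset; :meth:`InvasionModel.fit` computes regime summaries, the
regime contrast with a within-line permutation test, and — given a
scenario grid or precomputed grid summaries — ranks every
(scenario, alpha) simulation cell against each regime's observed
trajectory.  The returned :class:`InvasionResults` carries the
estimates and exposes ``summary()`` and ``plot()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import analysis
from .datasets import read_dataset
from .scenarios import ScenarioGrid, TrajectorySummary, run_grid
from .simulate import SimulationConfig

__all__ = ["InvasionModel", "InvasionResults"]


class InvasionModel:
    """Scenario-fit model for a multigenerational invasion dataset.

    Parameters
    ----------
    data
        Tidy invasion dataset (columns regime, line, replicate,
        generation, n_wt_phenotype, n_rd_phenotype; generations 2-8).
    grid
        Scenario grid to simulate when fitting.  Ignored when
        precomputed ``summaries`` are passed to :meth:`fit`.
    config
        Demographic constants of the simulated experiment.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        grid: ScenarioGrid | None = None,
        config: SimulationConfig | None = None,
    ):
        self.data = data
        self.grid = grid or ScenarioGrid()
        self.config = config or SimulationConfig()

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "InvasionModel":
        return cls(read_dataset(path, kind="invasion"), **kwargs)

    def fit(
        self,
        summaries: Sequence[TrajectorySummary] | None = None,
        n_permutations: int = 10_000,
        seed: int = 0,
    ) -> "InvasionResults":
        """Fit the model.

        Runs the scenario grid (unless precomputed ``summaries`` are
        supplied), summarises the data by regime, tests the regime
        contrast by permutation, and ranks every simulated cell against
        each regime trajectory.
        """
        rng = np.random.default_rng(seed)
        summary = analysis.regime_summary(self.data)
        difference, argmax_gen = analysis.regime_difference(summary)
        perm = analysis.permutation_regime_test(
            self.data, n_permutations=n_permutations, rng=rng
        )
        if summaries is None:
            from dataclasses import replace

            summaries = run_grid(self.grid, replace(self.config, seed=seed))
        fits = {
            regime: analysis.scenario_fit(summary, summaries, regime)
            for regime in ("Monogamy", "Polyandry")
        }
        return InvasionResults(
            model=self,
            regime_summary=summary,
            difference=difference,
            max_difference_generation=argmax_gen,
            permutation=perm,
            scenario_fits=fits,
            grid_summaries=list(summaries),
        )


@dataclass
class InvasionResults:
    """Fitted results: summaries, regime contrast and scenario ranking."""

    model: InvasionModel
    regime_summary: pd.DataFrame
    difference: pd.Series
    max_difference_generation: int
    permutation: analysis.PermutationResult
    scenario_fits: dict[str, pd.DataFrame]
    grid_summaries: list[TrajectorySummary]

    def best_cell(self, regime: str) -> tuple[str, float]:
        """(scenario, alpha) of the best-fitting cell for a regime."""
        top = self.scenario_fits[regime].iloc[0]
        return str(top["scenario"]), float(top["alpha"])

    def summary(self) -> str:
        """Human-readable report of the fit."""
        lines = ["Invasion scenario-fit results", "=" * 34, ""]
        lines.append("Mean proportion WT phenotype (SE) by regime and generation:")
        table = self.regime_summary.reset_index()
        for regime in ("Monogamy", "Polyandry"):
            sub = table[table["regime"] == regime]
            row = "  ".join(
                f"g{int(g)}={m:.2f}({s:.2f})"
                for g, m, s in zip(sub["generation"], sub["mean"], sub["se"])
            )
            lines.append(f"  {regime:<10} {row}")
        lines.append("")
        lines.append(
            "Regime difference (Polyandry - Monogamy): "
            + ", ".join(f"g{int(g)}={d:+.2f}" for g, d in self.difference.items())
        )
        lines.append(
            f"Largest difference at generation {self.max_difference_generation} "
            f"({self.difference.max():+.2f})"
        )
        kind = "exact" if self.permutation.exact else "Monte Carlo"
        lines.append(
            f"Within-line permutation test ({kind}, "
            f"{self.permutation.n_permutations} permutations): "
            f"statistic={self.permutation.statistic:+.3f}, "
            f"p={self.permutation.pvalue:.4g}"
        )
        lines.append("")
        for regime, fits in self.scenario_fits.items():
            top = fits.head(3)
            best = ", ".join(
                f"#{int(r['rank'])} scenario {r['scenario']} "
                f"(alpha={r['alpha']:g}, RMSE={r['distance']:.3f})"
                for _, r in top.iterrows()
            )
            lines.append(f"Best-fitting simulations for {regime}: {best}")
        return "\n".join(lines)

    def to_report(self) -> dict:
        """JSON-serialisable report of all fitted quantities."""
        return {
            "regime_summary": [
                {
                    "regime": regime,
                    "generation": int(gen),
                    "mean": float(row["mean"]),
                    "se": float(row["se"]),
                    "n_populations": int(row["n_populations"]),
                }
                for (regime, gen), row in self.regime_summary.iterrows()
            ],
            "difference": {int(g): float(d) for g, d in self.difference.items()},
            "max_difference_generation": self.max_difference_generation,
            "permutation_test": {
                "statistic": self.permutation.statistic,
                "pvalue": self.permutation.pvalue,
                "n_permutations": self.permutation.n_permutations,
                "exact": self.permutation.exact,
                "note": "within-line label permutation; not a mixed-model fit",
            },
            "scenario_fits": {
                regime: fits.to_dict(orient="records")
                for regime, fits in self.scenario_fits.items()
            },
        }

    def plot(self, ax=None, regimes: Sequence[str] = ("Monogamy", "Polyandry")):
        """Observed regime trajectories over the best-fitting simulation band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4.5))
        colors = {"Monogamy": "tab:blue", "Polyandry": "tab:red"}
        by_key = {(s.scenario, s.alpha): s for s in self.grid_summaries}
        for regime in regimes:
            sub = self.regime_summary.loc[regime]
            ax.errorbar(
                sub.index,
                sub["mean"],
                yerr=sub["se"],
                marker="o",
                color=colors.get(regime),
                label=f"{regime} (observed)",
            )
            cell = by_key.get(self.best_cell(regime))
            if cell is not None:
                gens = np.arange(len(cell.median))
                ax.plot(
                    gens,
                    cell.median,
                    "--",
                    color=colors.get(regime),
                    alpha=0.7,
                    label=f"{regime} best fit: {cell.scenario}, alpha={cell.alpha:g}",
                )
                ax.fill_between(
                    gens, cell.q05, cell.q95, color=colors.get(regime), alpha=0.12
                )
        ax.set_xlabel("generation")
        ax.set_ylabel("proportion WT phenotype")
        ax.set_ylim(0, 1)
        ax.legend(fontsize=8)
        return ax
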
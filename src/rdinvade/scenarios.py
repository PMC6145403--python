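"""Scenario grid: fitness-component combinations x alpha x replicates.

Eight scenarios cover every combination of the three fitness components:

    i     equal fitness (neutral)
    ii    male reproductive success only
    iii   female reproductive success only
    iv    male and female reproductive success
    v     offspring performance and viability only
    vi    male reproductive success and offspring viability
    vii   female reproductive success and offspring viability
    viii  male and female reproductive success, and offspring viability

Scenario i ignores the alpha grid (it is neutral by construction); every
other scenario is crossed with each alpha level.  Each cell of the grid
is run for a fixed number of replicates and summarised per generation by
the median and the 5-95% quantiles of the WT-homozygote proportion.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .simulate import FitnessScheme, SimulationConfig, run_trajectory

__all__ = [
    "SCENARIO_EFFECTS",
    "SCENARIO_LABELS",
    "scheme_for",
    "ScenarioGrid",
    "TrajectorySummary",
    "build_scenario_grid",
    "run_grid",
    "run_replicates",
    "replicate_rng",
    "summaries_to_frame",
    "summaries_from_frame",
]

# (male_effect, female_effect, offspring_effect) per scenario label
SCENARIO_EFFECTS: dict[str, tuple[bool, bool, bool]] = {
    "i": (False, False, False),
    "ii": (True, False, False),
    "iii": (False, True, False),
    "iv": (True, True, False),
    "v": (False, False, True),
    "vi": (True, False, True),
    "vii": (False, True, True),
    "viii": (True, True, True),
}
SCENARIO_LABELS = tuple(SCENARIO_EFFECTS)

DEFAULT_ALPHAS = (1.5, 2.0, 5.0, 10.0)


def scheme_for(scenario: str, alpha: float = 1.0) -> FitnessScheme:
    """FitnessScheme for a scenario label; scenario i is always neutral."""
    if scenario not in SCENARIO_EFFECTS:
        raise ValueError(
            f"unknown scenario {scenario!r}; expected one of {SCENARIO_LABELS}"
        )
    male, female, offspring = SCENARIO_EFFECTS[scenario]
    if scenario == "i":
        alpha = 1.0
    return FitnessScheme(
        alpha=alpha,
        male_effect=male,
        female_effect=female,
        offspring_effect=offspring,
    )


@dataclass(frozen=True)
class GridCell:
    scenario: str
    alpha: float
    survival_fraction: float

    @property
    def scheme(self) -> FitnessScheme:
        return scheme_for(self.scenario, self.alpha)


@dataclass(frozen=True)
class ScenarioGrid:
    """The full set of (scenario, alpha, survival fraction) cells to run."""

    scenarios: tuple[str, ...] = SCENARIO_LABELS
    alphas: tuple[float, ...] = DEFAULT_ALPHAS
    n_replicates: int = 500
    survival_fractions: tuple[float, ...] = (0.30,)

    def cells(self) -> Iterator[GridCell]:
        """Cells in fixed order: survival-major, scenario, then alpha.

        Scenario i appears once per survival fraction (alpha is
        irrelevant under neutrality); every other scenario crosses with
        every alpha.
        """
        for sf in self.survival_fractions:
            for scen in self.scenarios:
                if scen == "i":
                    yield GridCell("i", 1.0, sf)
                else:
                    for a in self.alphas:
                        yield GridCell(scen, a, sf)

    @property
    def n_cells(self) -> int:
        return sum(1 for _ in self.cells())


def build_scenario_grid(
    scenarios: Sequence[str] | None = None,
    alphas: Sequence[float] | None = None,
    n_replicates: int = 500,
    survival_fractions: Sequence[float] | None = None,
) -> ScenarioGrid:
    """Build a grid, validating scenario names.

    Defaults reproduce the standard design: 1 neutral cell plus
    7 scenarios x 4 alpha levels = 29 cells at 30% offspring survival,
    500 replicates each.
    """
    scenarios = tuple(scenarios) if scenarios is not None else SCENARIO_LABELS
    for s in scenarios:
        if s not in SCENARIO_EFFECTS:
            raise ValueError(
                f"unknown scenario {s!r}; expected one of {SCENARIO_LABELS}"
            )
    alphas = tuple(float(a) for a in (alphas if alphas is not None else DEFAULT_ALPHAS))
    if any(a <= 0 for a in alphas):
        raise ValueError("alpha values must be positive")
    survival_fractions = tuple(
        float(s) for s in (survival_fractions if survival_fractions is not None else (0.30,))
    )
    return ScenarioGrid(
        scenarios=scenarios,
        alphas=alphas,
        n_replicates=n_replicates,
        survival_fractions=survival_fractions,
    )


@dataclass
class TrajectorySummary:
    """Replicate summary of one grid cell.

    Arrays are indexed by generation 0..n_generations; values are the
    median and 5-95% quantiles (linear interpolation) of the
    WT-homozygote proportion across replicates.
    """

    scenario: str
    alpha: float
    survival_fraction: float
    n_replicates: int
    median: np.ndarray
    q05: np.ndarray
    q95: np.ndarray
    mean: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scenario": self.scenario,
                "alpha": self.alpha,
                "survival_fraction": self.survival_fraction,
                "generation": np.arange(len(self.median)),
                "median": self.median,
                "q05": self.q05,
                "q95": self.q95,
                "mean": self.mean,
                "n_replicates": self.n_replicates,
            }
        )


def replicate_rng(
    seed: int, scenario: str, alpha: float, survival_fraction: float, replicate: int
) -> np.random.Generator:
    """Deterministic per-replicate stream.

    The stream depends only on the master seed and the cell coordinates,
    never on grid composition or replicate count, so (a) any replicate
    is reproducible in isolation and (b) running fewer replicates
    reproduces a prefix of the full replicate set.
    """
    entropy = [
        int(seed),
        SCENARIO_LABELS.index(scenario),
        int(round(alpha * 1000)),
        int(round(survival_fraction * 1000)),
        int(replicate),
    ]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def run_replicates(
    cell: GridCell, config: SimulationConfig, n_replicates: int
) -> np.ndarray:
    """WT-homozygote proportion per (replicate, generation) for one cell."""
    config = _with_survival(config, cell.survival_fraction)
    scheme = cell.scheme
    out = np.empty((n_replicates, config.n_generations + 1))
    for r in range(n_replicates):
        rng = replicate_rng(
            config.seed, cell.scenario, cell.alpha, cell.survival_fraction, r
        )
        out[r] = run_trajectory(scheme, config, rng).prop_wt_homozygote
    return out


def _with_survival(config: SimulationConfig, survival_fraction: float) -> SimulationConfig:
    if config.survival_fraction == survival_fraction:
        return config
    from dataclasses import replace

    return replace(config, survival_fraction=survival_fraction)


def _summarise(cell: GridCell, props: np.ndarray, n_replicates: int) -> TrajectorySummary:
    return TrajectorySummary(
        scenario=cell.scenario,
        alpha=cell.alpha,
        survival_fraction=cell.survival_fraction,
        n_replicates=n_replicates,
        median=np.quantile(props, 0.5, axis=0),
        q05=np.quantile(props, 0.05, axis=0),
        q95=np.quantile(props, 0.95, axis=0),
        mean=props.mean(axis=0),
    )


def run_grid(
    grid: ScenarioGrid,
    config: SimulationConfig | None = None,
    out_path: str | Path | None = None,
    progress: bool = False,
) -> list[TrajectorySummary]:
    """Run every cell of the grid and summarise per generation.

    Cells execute in the fixed grid order; replicate streams derive from
    ``config.seed`` and the cell coordinates, so a full run is
    bit-reproducible.  If ``out_path`` is given, each cell's summary
    rows are appended to the CSV as the cell completes.
    """
    config = config or SimulationConfig()
    summaries: list[TrajectorySummary] = []
    out_path = Path(out_path) if out_path is not None else None
    first_write = True
    for cell in grid.cells():
        try:
            props = run_replicates(cell, config, grid.n_replicates)
        except Exception as exc:  # annotate failures with the cell identity
            raise RuntimeError(
                f"grid cell scenario={cell.scenario} alpha={cell.alpha} "
                f"survival={cell.survival_fraction} failed"
            ) from exc
        summary = _summarise(cell, props, grid.n_replicates)
        summaries.append(summary)
        if out_path is not None:
            summary.to_frame().to_csv(
                out_path, mode="w" if first_write else "a", header=first_write, index=False
            )
            first_write = False
        if progress:
            print(
                f"cell scenario={cell.scenario} alpha={cell.alpha} "
                f"survival={cell.survival_fraction} done"
            )
    return summaries


def summaries_to_frame(summaries: Sequence[TrajectorySummary]) -> pd.DataFrame:
    """Tidy long-format frame of grid summaries."""
    return pd.concat([s.to_frame() for s in summaries], ignore_index=True)


def summaries_from_frame(frame: pd.DataFrame) -> list[TrajectorySummary]:
    """Inverse of :func:`summaries_to_frame`."""
    required = {
        "scenario",
        "alpha",
        "survival_fraction",
        "generation",
        "median",
        "q05",
        "q95",
        "mean",
        "n_replicates",
    }
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"summary frame is missing columns: {sorted(missing)}")
    out = []
    keys = ["scenario", "alpha", "survival_fraction"]
    for (scen, alpha, sf), sub in frame.groupby(keys, sort=False):
        sub = sub.sort_values("generation")
        out.append(
            TrajectorySummary(
                scenario=str(scen),
                alpha=float(alpha),
                survival_fraction=float(sf),
                n_replicates=int(sub["n_replicates"].iloc[0]),
                median=sub["median"].to_numpy(),
                q05=sub["q05"].to_numpy(),
                q95=sub["q95"].to_numpy(),
                mean=sub["mean"].to_numpy(),
            )
        )
    return out
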
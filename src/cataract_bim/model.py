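"""Model/Results facade over the budget-impact machinery.

:class:`BudgetImpactModel` wraps a :class:`~cataract_bim.parameters.ScenarioConfig`;
``fit()`` evaluates the deterministic cohort model (nothing is statistically
estimated — the "fit" is an exact expectation computation) and returns a
:class:`BudgetImpactResults` carrying per-arm resource use and costs, the
incremental comparison, the throughput benefit, a ``summary()`` table, the
one-way sensitivity analysis, and the Monte-Carlo validation of the
expectations.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import reporting
from .cohort import ResourceUseSummary, resource_use
from .costing import (
    CostSummary,
    IncrementalResult,
    ThroughputSummary,
    arm_costs,
    incremental,
    throughput_benefit,
)
from .microsim import MicrosimSummary, OracleReport, oracle_check, simulate_cohort
from .parameters import ScenarioConfig, base_case, config_hash, load_scenario
from .sensitivity import TornadoEntry, one_way_dsa, plot_tornado, tornado_table

__all__ = ["BudgetImpactModel", "BudgetImpactResults"]


class BudgetImpactModel:
    """One-year, two-arm hospital budget-impact model of mydriasis strategy.

    Parameters
    ----------
    config
        Fully validated scenario.  Use :meth:`from_yaml` to read a scenario
        file or :meth:`base_case` for the packaged published inputs.

    Examples
    --------
    >>> results = BudgetImpactModel.base_case().fit()
    >>> round(results.incremental.costs.total_cost)
    -6249
    """

    def __init__(self, config: ScenarioConfig):
        self.config = config

    @classmethod
    def from_yaml(cls, path: str) -> "BudgetImpactModel":
        return cls(load_scenario(path))

    @classmethod
    def base_case(cls) -> "BudgetImpactModel":
        return cls(base_case())

    def fit(self) -> "BudgetImpactResults":
        """Evaluate the cohort model and return the results object."""
        cfg = self.config
        res = {w: resource_use(cfg.arm(w), cfg) for w in ("intervention", "reference")}
        costs = {
            w: arm_costs(res[w], cfg.arm(w), cfg) for w in ("intervention", "reference")
        }
        incr = incremental(
            (res["intervention"], costs["intervention"]),
            (res["reference"], costs["reference"]),
        )
        benefit = throughput_benefit(incr, cfg, costs["intervention"])
        return BudgetImpactResults(
            model=self,
            config=cfg,
            resource_use=res,
            costs=costs,
            incremental=incr,
            throughput=benefit,
        )

    run = fit  # alias: nothing is estimated, "run" reads naturally too


@dataclass
class BudgetImpactResults:
    """Evaluated budget impact of the intervention versus the reference."""

    model: BudgetImpactModel
    config: ScenarioConfig
    resource_use: dict[str, ResourceUseSummary]
    costs: dict[str, CostSummary]
    incremental: IncrementalResult
    throughput: ThroughputSummary

    @property
    def config_fingerprint(self) -> str:
        return config_hash(self.config)

    # -- tables --------------------------------------------------------

    def frames(self) -> dict[str, pd.DataFrame]:
        """Full-precision result tables keyed ``resource_use``/``costs``/``benefit``."""
        return {
            "resource_use": reporting.resource_frame(
                self.resource_use["intervention"],
                self.resource_use["reference"],
                self.incremental,
            ),
            "costs": reporting.cost_frame(
                self.costs["intervention"], self.costs["reference"], self.incremental
            ),
            "benefit": reporting.benefit_frame(self.throughput),
        }

    def rounded_frames(self) -> dict[str, pd.DataFrame]:
        return {k: reporting.round_for_display(v) for k, v in self.frames().items()}

    def summary(self) -> str:
        """Human-readable report (rounded views of the full-precision record)."""
        frames = self.rounded_frames()
        parts = [
            "Budget impact: intracameral mydriatic injection vs. topical drops",
            f"scenario fingerprint: {self.config_fingerprint}   "
            f"cohort: {self.config.n_patients} operations/year (GBP)",
            "",
            "Annual resource use",
            frames["resource_use"].to_string(),
            "",
            "Annual costs",
            frames["costs"].to_string(),
            "",
            "Hospital throughput benefit",
            frames["benefit"].to_string(),
        ]
        return "\n".join(parts)

    # -- sensitivity ---------------------------------------------------

    def sensitivity(self) -> list[TornadoEntry]:
        """One-way deterministic sensitivity analysis over the scenario bounds."""
        return one_way_dsa(self.config)

    def tornado_frame(self) -> pd.DataFrame:
        return tornado_table(self.sensitivity())

    def plot_tornado(self, path: str) -> str:
        return plot_tornado(
            self.sensitivity(), self.incremental.costs.total_cost, path
        )

    # -- simulation ----------------------------------------------------

    def simulate(self, n_replicates: int, seed: int) -> MicrosimSummary:
        """Patient-level Monte-Carlo replicates of the annual cohort."""
        return simulate_cohort(self.config, n_replicates, seed)

    def check_against_simulation(self, n_replicates: int, seed: int) -> OracleReport:
        """Validate the cohort expectations against the microsimulation."""
        return oracle_check(self.config, self.simulate(n_replicates, seed))
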
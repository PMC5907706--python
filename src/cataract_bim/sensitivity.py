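"""One-way deterministic sensitivity analysis (tornado) on incremental cost.

Each bounded input is set to its low and then its high value with every
other input held at base, the full model is rebuilt each time, and the
incremental **total** annual cost (intervention minus reference — the
quantity a tornado diagram's "no economic impact" line refers to) is
recorded.  Entries are ranked by span, the absolute width of the induced
incremental-cost interval; an entry flips sign when its low and high
incrementals straddle zero, i.e. the parameter alone can overturn the
base-case conclusion.

Bounds live in the scenario (``dsa_bounds``) and are evaluated exactly as
given — including published intervals that are not symmetric or do not even
bracket the base value.  A grouped entry (shared drug price, the rescue
distribution switched as one scenario) moves all of its paths together.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort import resource_use
from .costing import arm_costs, incremental
from .parameters import DsaBound, ScenarioConfig, get_parameter, set_parameter

__all__ = ["TornadoEntry", "one_way_dsa", "tornado_table", "plot_tornado"]


@dataclass(frozen=True)
class TornadoEntry:
    """Low/high incremental-cost pair for one varied input."""

    parameter_path: str
    base_value: float | None  # None for grouped (multi-path) entries
    low_value: float | None
    high_value: float | None
    incremental_at_low: float
    incremental_at_high: float

    @property
    def span(self) -> float:
        return abs(self.incremental_at_high - self.incremental_at_low)

    @property
    def sign_flip(self) -> bool:
        return self.incremental_at_low * self.incremental_at_high < 0.0


def incremental_total_cost(config: ScenarioConfig) -> float:
    """Intervention-minus-reference total annual cost for one configuration."""
    iv_res = resource_use(config.intervention, config)
    rf_res = resource_use(config.reference, config)
    incr = incremental(
        (iv_res, arm_costs(iv_res, config.intervention, config)),
        (rf_res, arm_costs(rf_res, config.reference, config)),
    )
    return incr.costs.total_cost


def _apply_moves(config: ScenarioConfig, bound: DsaBound, which: str) -> ScenarioConfig:
    idx = 1 if which == "low" else 2
    out = config
    for move in bound.moves:
        out = set_parameter(out, move[0], move[idx])
    return out


def one_way_dsa(config: ScenarioConfig) -> list[TornadoEntry]:
    """Sweep every bounded input one at a time; return entries by descending span.

    The base configuration is never mutated: each evaluation works on a
    fresh copy produced by ``set_parameter``.
    """
    entries = []
    for bound in config.dsa_bounds:
        single = len(bound.moves) == 1
        entries.append(
            TornadoEntry(
                parameter_path=bound.name,
                base_value=get_parameter(config, bound.moves[0][0]) if single else None,
                low_value=bound.moves[0][1] if single else None,
                high_value=bound.moves[0][2] if single else None,
                incremental_at_low=incremental_total_cost(
                    _apply_moves(config, bound, "low")
                ),
                incremental_at_high=incremental_total_cost(
                    _apply_moves(config, bound, "high")
                ),
            )
        )
    entries.sort(key=lambda e: (-e.span, e.parameter_path))
    return entries


def tornado_table(entries: list[TornadoEntry]) -> pd.DataFrame:
    """Tornado-ordered table: one row per entry, widest span first.

    Ties in span break lexicographically by parameter path, so the ordering
    is stable and reruns are byte-identical.
    """
    rows = [
        {
            "parameter_path": e.parameter_path,
            "base_value": e.base_value,
            "low_value": e.low_value,
            "high_value": e.high_value,
            "incremental_at_low": e.incremental_at_low,
            "incremental_at_high": e.incremental_at_high,
            "span": e.span,
            "sign_flip": e.sign_flip,
        }
        for e in sorted(entries, key=lambda e: (-e.span, e.parameter_path))
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "parameter_path", "base_value", "low_value", "high_value",
            "incremental_at_low", "incremental_at_high", "span", "sign_flip",
        ],
    )


def plot_tornado(
    entries: list[TornadoEntry],
    base_incremental: float,
    path: str,
    max_entries: int = 15,
):
    """Render a tornado diagram with a zero-incremental reference line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = sorted(entries, key=lambda e: (-e.span, e.parameter_path))[:max_entries]
    ordered = ordered[::-1]  # widest bar on top
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(ordered) + 1.5))
    for i, e in enumerate(ordered):
        lo = min(e.incremental_at_low, e.incremental_at_high)
        hi = max(e.incremental_at_low, e.incremental_at_high)
        ax.barh(i, hi - lo, left=lo, height=0.6, color="#4878a8")
    ax.axvline(0.0, color="green", lw=1.5, label="no economic impact")
    ax.axvline(base_incremental, color="grey", lw=1.5, ls="--", label="base case")
    ax.set_yticks(range(len(ordered)))
    ax.set_yticklabels([e.parameter_path for e in ordered], fontsize=8)
    ax.set_xlabel("incremental total cost (GBP/year)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
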
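"""Report rendering: annual resource-use, cost, and benefit tables.

All model arithmetic is carried at full precision; rounding happens here
and only here, following the conventions of published budget-impact tables:
hours and counts to 2 decimals, annual pounds to the nearest pound,
per-patient pounds to pence.  Full-precision values are always available in
the machine-readable frames / JSON sidecar, so rounded cells are views,
never inputs to further arithmetic.
"""

from __future__ import annotations

import json
from dataclasses import fields

import pandas as pd

from .cohort import ResourceUseSummary
from .costing import CostSummary, IncrementalResult, ThroughputSummary

__all__ = [
    "resource_frame",
    "cost_frame",
    "benefit_frame",
    "round_for_display",
    "frames_to_json",
]

_COLS = ["intervention", "reference", "difference"]

# pounds rounded to integers; everything else to 2 decimals
_POUND_ROWS = {
    "nurse_cost",
    "surgeon_cost",
    "work_related_cost",
    "drug_acquisition_cost",
    "rescue_cost",
    "treatment_related_cost",
    "total_cost",
    "additional_revenue",
    "expected_net_benefit",
}


def resource_frame(
    intervention: ResourceUseSummary,
    reference: ResourceUseSummary,
    incr: IncrementalResult,
) -> pd.DataFrame:
    """Full-precision annual resource use, arms side by side."""
    rows = [f.name for f in fields(ResourceUseSummary)]
    return pd.DataFrame(
        {
            "intervention": [getattr(intervention, r) for r in rows],
            "reference": [getattr(reference, r) for r in rows],
            "difference": [getattr(incr.resource_use, r) for r in rows],
        },
        index=rows,
    )


def cost_frame(
    intervention: CostSummary, reference: CostSummary, incr: IncrementalResult
) -> pd.DataFrame:
    """Full-precision annual costs, arms side by side."""
    rows = [f.name for f in fields(CostSummary)]
    return pd.DataFrame(
        {
            "intervention": [getattr(intervention, r) for r in rows],
            "reference": [getattr(reference, r) for r in rows],
            "difference": [getattr(incr.costs, r) for r in rows],
        },
        index=rows,
    )


def benefit_frame(throughput: ThroughputSummary) -> pd.DataFrame:
    """Full-precision hospital throughput benefit."""
    rows = [f.name for f in fields(ThroughputSummary)]
    return pd.DataFrame({"value": [getattr(throughput, r) for r in rows]}, index=rows)


def round_for_display(frame: pd.DataFrame) -> pd.DataFrame:
    """Apply the table rounding conventions row by row."""
    out = frame.copy()
    for row in out.index:
        if row in _POUND_ROWS:
            out.loc[row] = out.loc[row].round(0)
        else:  # hours, counts, per-patient pounds, operations gained
            out.loc[row] = out.loc[row].round(2)
    return out


def frames_to_json(frames: dict[str, pd.DataFrame], path: str) -> None:
    """Dump full-precision frames as one JSON document."""
    payload = {name: df.to_dict(orient="index") for name, df in frames.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
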
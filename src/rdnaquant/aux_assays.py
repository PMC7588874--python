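"""Small quantitative stages: RT-qPCR relative expression and yeast
chronological-life-span survival.

Relative expression uses the delta-delta-Cq form with a fixed amplification
efficiency (2.0 by default, i.e. no efficiency correction) and is computed
separately against each housekeeping gene — never averaged across them,
since housekeeping transcripts may themselves drift with age.

Chronological life span is CFU survival of stationary-phase yeast,
normalized to the day-3 plating.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .models import SurvivalCurve

__all__ = [
    "chronological_survival",
    "premature_to_mature_ratio",
    "relative_expression",
    "relative_to_group_mean",
    "summarize_survival",
]


def relative_expression(
    target_cq: float,
    housekeeping_cq: Optional[float],
    efficiency: float = 2.0,
    reference_sample_delta: float = 0.0,
) -> float:
    """Normalized expression relative to a reference sample.

    dCq = target_cq - housekeeping_cq; the relative amount is
    efficiency ** -(dCq - dCq_reference).  Adding a constant to both Cq
    values (an instrument offset) cancels exactly.
    """
    if housekeeping_cq is None or not np.isfinite(housekeeping_cq):
        raise ValueError("missing housekeeping measurement")
    if not 1.0 < efficiency <= 2.2:
        raise ValueError(f"efficiency must be in (1, 2.2], got {efficiency}")
    delta = target_cq - housekeeping_cq
    return float(efficiency ** (-(delta - reference_sample_delta)))


def premature_to_mature_ratio(rel_pre45s: float, rel_28s: float) -> float:
    """Ratio of newly synthesized pre-45S to mature 28S relative amounts."""
    if rel_28s <= 0:
        raise ValueError(f"rel_28s must be > 0, got {rel_28s}")
    return rel_pre45s / rel_28s


def relative_to_group_mean(
    values: Mapping[str, float], reference_ids: Sequence[str]
) -> dict[str, float]:
    """Scale a per-sample statistic so the reference-group mean is exactly 1."""
    if not reference_ids:
        raise ValueError("reference_ids must be non-empty")
    missing = [s for s in reference_ids if s not in values]
    if missing:
        raise ValueError(f"reference sample(s) {missing} missing from values")
    ref_mean = float(np.mean([values[s] for s in reference_ids]))
    if ref_mean == 0:
        raise ValueError("reference-group mean is zero; cannot normalize")
    return {s: v / ref_mean for s, v in values.items()}


def chronological_survival(series: Sequence[tuple[int, int]]) -> SurvivalCurve:
    """Survival curve from (day, CFU) platings, anchored at day 3.

    Days must be strictly increasing and include day 3 with a positive
    count.  Survival above 1 (growth after day 3) is kept and flagged via
    ``SurvivalCurve.exceeds_one``, never clipped.
    """
    if not series:
        raise ValueError("empty CFU series")
    days = [int(d) for d, _ in series]
    cfu = [int(c) for _, c in series]
    if any(b <= a for a, b in zip(days, days[1:])):
        raise ValueError("days must be strictly increasing")
    if any(d < 3 for d in days):
        raise ValueError("chronological ageing is scored from day 3 onward")
    if 3 not in days:
        raise ValueError("missing day 3 plating (normalization anchor)")
    if any(c < 0 for c in cfu):
        raise ValueError("CFU counts must be >= 0")
    anchor = cfu[days.index(3)]
    if anchor <= 0:
        raise ValueError("day 3 CFU must be > 0")
    survival = tuple(c / anchor for c in cfu)
    return SurvivalCurve(days=tuple(days), cfu=tuple(cfu), survival=survival)


def summarize_survival(curves: Sequence[SurvivalCurve]) -> pd.DataFrame:
    """Per-day mean and SD of survival over replicate experiments."""
    if not curves:
        raise ValueError("no curves to summarize")
    rows = []
    for i, curve in enumerate(curves):
        for d, s in zip(curve.days, curve.survival):
            rows.append({"replicate": i, "day": d, "survival": s})
    df = pd.DataFrame(rows)
    out = (
        df.groupby("day")["survival"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else np.nan, n="count")
        .reset_index()
    )
    return out
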
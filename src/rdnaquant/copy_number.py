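"""rDNA copy-number estimation from three independent assays.

* droplet digital PCR: Poisson inversion of the positive-droplet fraction,
  with a duplex single-copy reference (RNase P style, 2 copies per diploid
  cell) converting concentration to copies per cell;
* single-cell qPCR: inversion of a serial-dilution standard curve;
* whole-genome sequencing: the fraction of reads mapping to the rDNA array.

Cohorts are summarized per mouse as mean, sample SD, and coefficient of
variation (SD/mean) of the per-cell copy numbers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .models import CohortStats, DropletCounts, MouseSample, StandardCurve

__all__ = [
    "DdpcrEstimate",
    "SaturatedAssayError",
    "cohort_stats",
    "ddpcr_copies_per_cell",
    "ddpcr_lambda",
    "fit_standard_curve",
    "group_summary",
    "qpcr_copies_single_cell",
    "wgs_copy_number",
]


class SaturatedAssayError(ValueError):
    """Every droplet is positive: the mean occupancy is unidentifiable."""


@dataclass(frozen=True)
class DdpcrEstimate:
    """Mean copies per droplet with a delta-method 95% CI."""

    value: float
    ci_low: float
    ci_high: float


def ddpcr_lambda(counts: DropletCounts) -> DdpcrEstimate:
    """Mean template copies per droplet from partition counts.

    With positive fraction p, occupancy is Poisson and lambda = -ln(1 - p).
    The 95% CI propagates the binomial SE of p through the log transform
    (SE_lambda = SE_p / (1 - p)).
    """
    if counts.n_positive == counts.n_total:
        raise SaturatedAssayError(
            f"all {counts.n_total} droplets positive; dilute and repeat"
        )
    p = counts.n_positive / counts.n_total
    lam = -math.log1p(-p)
    se_p = math.sqrt(p * (1.0 - p) / counts.n_total)
    se_lam = se_p / (1.0 - p)
    return DdpcrEstimate(
        value=lam,
        ci_low=max(0.0, lam - 1.96 * se_lam),
        ci_high=lam + 1.96 * se_lam,
    )


def ddpcr_copies_per_cell(
    target: DropletCounts,
    reference: DropletCounts,
    reference_copies_per_cell: float = 2.0,
) -> float:
    """Target copies per cell via the duplex single-copy reference.

    copies = reference_copies_per_cell * lambda_target / lambda_reference.
    """
    lam_t = ddpcr_lambda(target).value
    lam_r = ddpcr_lambda(reference).value
    if lam_r == 0.0:
        raise ValueError("no reference signal: all reference droplets negative")
    return reference_copies_per_cell * lam_t / lam_r


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Least-squares line of Cq on log10(known copies).

    Needs at least three dilution points with nonzero spread; a span under
    two decades only warns (the fit is still defined, just poorly leveraged).
    """
    if len(points) < 3:
        raise ValueError(f"need >= 3 dilution points, got {len(points)}")
    copies = np.array([c for c, _ in points], dtype=float)
    cq = np.array([q for _, q in points], dtype=float)
    if (copies <= 0).any():
        raise ValueError("known copies must be > 0")
    x = np.log10(copies)
    if np.ptp(x) == 0.0:
        raise ValueError("zero variance in copies: a single dilution level cannot anchor a curve")
    if np.ptp(x) < 2.0:
        warnings.warn(
            f"dilution series spans only {np.ptp(x):.2f} log10 units (< 2)",
            stacklevel=2,
        )
    fit = stats.linregress(x, cq)
    if fit.slope >= 0:
        raise ValueError(f"fitted slope {fit.slope:.3f} is not negative; not an amplification curve")
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def qpcr_copies_single_cell(cq: Optional[float], curve: StandardCurve) -> float:
    """Copies implied by one Cq on the calibrated curve.

    The no-amplification sentinel (``None``) is reported as 0 copies; the
    flag survives in report tables as an explicit zero with no Cq.
    """
    if cq is None:
        return 0.0
    if not math.isfinite(cq):
        raise ValueError(f"Cq must be finite, got {cq}")
    return float(10.0 ** ((cq - curve.intercept) / curve.slope))


def cohort_stats(samples: Iterable[MouseSample]) -> list[CohortStats]:
    """Per-mouse mean, sample SD (n-1) and CV of per-cell copy numbers.

    A single-cell mouse gets ``None`` for SD and CV (missing, not zero).
    """
    out = []
    for s in samples:
        copies = s.copy_numbers
        n = len(copies)
        mean = float(np.mean(copies))
        if n >= 2:
            sd = float(np.std(copies, ddof=1))
            cv = sd / mean if mean > 0 else None
        else:
            sd = None
            cv = None
        out.append(
            CohortStats(
                mouse_id=s.mouse_id,
                strain=s.strain,
                age_group=s.age_group,
                n_cells=n,
                mean_copies=mean,
                sd_copies=sd,
                cv=cv,
            )
        )
    return out


def group_summary(per_mouse: Sequence[CohortStats]) -> dict[str, dict[str, float]]:
    """Grand means per age group: mean of per-mouse means and of per-mouse CVs."""
    groups: dict[str, dict[str, list[float]]] = {}
    for st in per_mouse:
        g = groups.setdefault(st.age_group, {"mean_copies": [], "cv": []})
        g["mean_copies"].append(st.mean_copies)
        if st.cv is not None:
            g["cv"].append(st.cv)
    return {
        age: {
            "mean_copies": float(np.mean(v["mean_copies"])),
            "cv": float(np.mean(v["cv"])) if v["cv"] else float("nan"),
            "n_mice": len(v["mean_copies"]),
        }
        for age, v in groups.items()
    }


def wgs_copy_number(
    rdna_reads: int,
    total_mapped_reads: int,
    unit_length: float,
    non_rdna_genome_length: Optional[float] = None,
    total_genome_length: Optional[float] = None,
    mode: str = "self_consistent",
) -> float:
    """Copies per cell from the rDNA read fraction f.

    ``self_consistent`` (default) accounts for the rDNA array's own mass in
    the denominator: copies = f * G_non / ((1 - f) * unit_length), the exact
    inverse of f = c*u / (G_non + c*u).  ``simple`` treats the genome length
    as fixed: copies = f * G_total / unit_length.
    """
    if total_mapped_reads <= 0:
        raise ValueError(f"total_mapped_reads must be > 0, got {total_mapped_reads}")
    if not 0 <= rdna_reads <= total_mapped_reads:
        raise ValueError("rdna_reads must be in [0, total_mapped_reads]")
    f = rdna_reads / total_mapped_reads
    if mode == "self_consistent":
        if non_rdna_genome_length is None:
            raise ValueError("self_consistent mode needs non_rdna_genome_length")
        if f == 1.0:
            raise ValueError("rDNA fraction of 1 has no finite self-consistent solution")
        return f * non_rdna_genome_length / ((1.0 - f) * unit_length)
    if mode == "simple":
        if total_genome_length is None:
            raise ValueError("simple mode needs total_genome_length")
        return f * total_genome_length / unit_length
    raise ValueError(f"unknown mode {mode!r}; use 'self_consistent' or 'simple'")
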
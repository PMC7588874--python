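"""Core data containers shared across the pipeline.

The containers model one rDNA repeat unit (restriction-site geometry, the
Southern probe interval, and known per-copy sequence variants), synthetic
mouse cohorts with per-cell copy numbers and per-copy chromatin/sequence
states, and the derived quantities produced by the assay modules (droplet
counts, qPCR standard curves, pileups, mutation-rate tracks, calls).

All coordinates are 1-based and inclusive unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

AGE_GROUPS = ("young", "old")

#: Pileup count columns, in storage order.
PILEUP_COLUMNS = ("A", "C", "G", "T", "ins", "del")


@dataclass(frozen=True)
class RestrictionSite:
    """One recognition site on the repeat unit."""

    enzyme: str
    position: int  # 1-based bp; the cut is placed immediately before it
    methylation_sensitive: bool = False


@dataclass(frozen=True)
class VariantDef:
    """A known per-copy variant on a locus-local coordinate (28S unless noted).

    ``frequency_*`` are the fractions of repeat copies carrying the
    alternative base in each age group.
    """

    position: int
    ref_base: str
    alt_base: str
    frequency_young: float
    frequency_old: float

    def __post_init__(self) -> None:
        for name in ("frequency_young", "frequency_old"):
            f = getattr(self, name)
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {f}")
        if self.position < 1:
            raise ValueError(f"variant position must be >= 1, got {self.position}")

    def frequency(self, age_group: str) -> float:
        if age_group not in AGE_GROUPS:
            raise ValueError(f"age_group must be one of {AGE_GROUPS}, got {age_group!r}")
        return self.frequency_young if age_group == "young" else self.frequency_old


@dataclass(frozen=True)
class RDNAUnitModel:
    """Geometry of a single rDNA repeat unit.

    ``bamhi2_position`` is the polymorphic internal BamHI site carried by a
    subset of copies; it is kept apart from the constitutive ``sites`` so a
    population can mix copies with and without it.
    """

    unit_length: int
    sites: tuple[RestrictionSite, ...]
    probe_interval: tuple[int, int]
    bamhi2_position: Optional[int] = None
    variants: tuple[VariantDef, ...] = ()

    def __post_init__(self) -> None:
        if self.unit_length < 1:
            raise ValueError(f"unit_length must be > 0, got {self.unit_length}")
        for site in self.sites:
            if not 1 <= site.position <= self.unit_length:
                raise ValueError(
                    f"site {site.enzyme} position {site.position} outside "
                    f"[1, {self.unit_length}] (field: sites)"
                )
        start, end = self.probe_interval
        if start > end:
            raise ValueError(
                f"probe_interval start {start} > end {end} (field: probe_interval)"
            )
        if not (1 <= start and end <= self.unit_length):
            raise ValueError(
                f"probe_interval {self.probe_interval} outside [1, {self.unit_length}] "
                "(field: probe_interval)"
            )
        if self.bamhi2_position is not None and not (
            1 <= self.bamhi2_position <= self.unit_length
        ):
            raise ValueError(
                f"bamhi2_position {self.bamhi2_position} outside "
                f"[1, {self.unit_length}] (field: bamhi2_position)"
            )

    @property
    def enzymes(self) -> frozenset[str]:
        names = {s.enzyme for s in self.sites}
        if self.bamhi2_position is not None:
            names.add("BamHI")
        return frozenset(names)

    def with_bamhi2(self, position: int) -> "RDNAUnitModel":
        return replace(self, bamhi2_position=position)

    def without_bamhi2(self) -> "RDNAUnitModel":
        return replace(self, bamhi2_position=None)


@dataclass(frozen=True)
class CellCopyProfile:
    """Per-cell rDNA state: copy number and per-copy state fractions."""

    cell_id: str
    copy_number: int
    bamhi2_fraction: float = 0.0
    methylated_fraction: float = 0.0
    active_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.copy_number < 0:
            raise ValueError(f"copy_number must be >= 0, got {self.copy_number}")
        for name in ("bamhi2_fraction", "methylated_fraction", "active_fraction"):
            f = getattr(self, name)
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {f}")


@dataclass(frozen=True)
class MouseSample:
    """One mouse with its sorted single cells."""

    mouse_id: str
    strain: str
    age_group: str
    sex: str
    cells: tuple[CellCopyProfile, ...]

    def __post_init__(self) -> None:
        if self.age_group not in AGE_GROUPS:
            raise ValueError(f"age_group must be one of {AGE_GROUPS}, got {self.age_group!r}")
        if len(self.cells) < 1:
            raise ValueError("a sample needs at least one cell")

    @property
    def copy_numbers(self) -> np.ndarray:
        return np.array([c.copy_number for c in self.cells], dtype=float)


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a two-age-group synthetic cohort.

    Copy-number means follow the single-cell measurements for the two inbred
    strains (471 copies/cell young BALB/cA-like, 1,025 young C57BL/6-like);
    the old/young mean ratio, the CVs, and the state fractions are free
    defaults chosen to reproduce the qualitative age effects (more copies,
    less cell-to-cell dispersion, more methylation, less transcription in
    old mice) and are all config-exposed.
    """

    strain: str = "BALB/cA-like"
    mean_copies_young: float = 471.0
    mean_copies_old: float = 565.2
    cv_young: float = 0.35
    cv_old: float = 0.20
    n_mice: int = 4
    cells_per_mouse: int = 96
    methylated_fraction_young: float = 0.10
    methylated_fraction_old: float = 0.25
    active_fraction_young: float = 0.50
    active_fraction_old: float = 0.35
    bamhi2_fraction_young: float = 0.50
    bamhi2_fraction_old: float = 0.35
    error_floor: float = 5e-4
    depth: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_copies_young <= 0 or self.mean_copies_old <= 0:
            raise ValueError("copy-number means must be > 0")
        if self.cv_young <= 0 or self.cv_old <= 0:
            raise ValueError("cv values must be > 0")
        if self.n_mice < 1:
            raise ValueError(f"n_mice must be >= 1, got {self.n_mice}")
        if self.cells_per_mouse < 1:
            raise ValueError(f"cells_per_mouse must be >= 1, got {self.cells_per_mouse}")
        if self.depth <= 0:
            raise ValueError(f"depth must be > 0, got {self.depth}")
        if not 0.0 <= self.error_floor <= 0.25:
            raise ValueError(f"error_floor must be in [0, 0.25], got {self.error_floor}")
        for name in (
            "methylated_fraction_young", "methylated_fraction_old",
            "active_fraction_young", "active_fraction_old",
            "bamhi2_fraction_young", "bamhi2_fraction_old",
        ):
            f = getattr(self, name)
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {f}")

    def group_fractions(self, age_group: str) -> dict[str, float]:
        suffix = "_young" if age_group == "young" else "_old"
        return {
            "bamhi2_fraction": getattr(self, "bamhi2_fraction" + suffix),
            "methylated_fraction": getattr(self, "methylated_fraction" + suffix),
            "active_fraction": getattr(self, "active_fraction" + suffix),
        }


@dataclass(frozen=True)
class DropletCounts:
    """Partition counts from one droplet digital PCR assay."""

    n_total: int
    n_positive: int

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError(f"n_total must be > 0, got {self.n_total}")
        if not 0 <= self.n_positive <= self.n_total:
            raise ValueError(
                f"n_positive must be in [0, {self.n_total}], got {self.n_positive}"
            )


@dataclass(frozen=True)
class StandardCurve:
    """qPCR calibration line: Cq = intercept + slope * log10(copies)."""

    slope: float
    intercept: float
    r_squared: float = 1.0

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError(f"slope must be < 0, got {self.slope}")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError(f"r_squared must be in [0, 1], got {self.r_squared}")
        e = self.efficiency
        if not 1.0 < e <= 2.2:
            raise ValueError(f"implied efficiency {e:.3f} outside (1, 2.2]")

    @property
    def efficiency(self) -> float:
        """Per-cycle amplification factor E = 10**(-1/slope)."""
        return 10.0 ** (-1.0 / self.slope)

    def predict_cq(self, copies: float) -> float:
        if copies <= 0:
            raise ValueError("copies must be > 0 to predict a Cq")
        return self.intercept + self.slope * float(np.log10(copies))


@dataclass(frozen=True)
class CohortStats:
    """Per-mouse copy-number summary; CV = SD / mean."""

    mouse_id: str
    strain: str
    age_group: str
    n_cells: int
    mean_copies: float
    sd_copies: Optional[float]
    cv: Optional[float]

    def __post_init__(self) -> None:
        if self.cv is not None and self.cv < 0:
            raise ValueError(f"cv must be >= 0, got {self.cv}")


@dataclass
class Pileup:
    """Per-position base/indel counts for one locus.

    ``counts`` has shape (L, 6) with columns A, C, G, T, ins, del.  Depth at
    a position is A+C+G+T+del: deleted reads span the position, inserted
    bases do not add to it (the insertion is recorded at the preceding
    reference position).
    """

    locus: str
    ref: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != len(PILEUP_COLUMNS):
            raise ValueError(f"counts must be (L, {len(PILEUP_COLUMNS)}), got {self.counts.shape}")
        if len(self.ref) != self.counts.shape[0]:
            raise ValueError(
                f"reference length {len(self.ref)} != counts rows {self.counts.shape[0]}"
            )
        if (self.counts < 0).any():
            raise ValueError("pileup counts must be >= 0")

    def __len__(self) -> int:
        return self.counts.shape[0]

    @property
    def depth(self) -> np.ndarray:
        """Reads covering each position (base calls plus deletions)."""
        return self.counts[:, :4].sum(axis=1) + self.counts[:, 5]


@dataclass(frozen=True)
class MutationRateTrack:
    """Per-position mutation rate for one sample and locus.

    ``rates`` pools substitutions, insertions and deletions; positions with
    zero depth are masked as NaN rather than reported as zero.
    """

    sample_id: str
    age_group: str
    locus: str
    rates: np.ndarray
    depth: np.ndarray
    substitution_rates: Optional[np.ndarray] = None
    insertion_rates: Optional[np.ndarray] = None
    deletion_rates: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        ok = ~np.isnan(self.rates)
        if ((self.rates[ok] < 0) | (self.rates[ok] > 1)).any():
            raise ValueError("rates must be in [0, 1] where defined")
        if self.rates.shape != self.depth.shape:
            raise ValueError("rates and depth must have the same shape")

    def __len__(self) -> int:
        return self.rates.shape[0]


@dataclass(frozen=True)
class AgeDifferentialCall:
    """A candidate age-differential site with its group evidence."""

    position: int
    young_rates: tuple[float, ...]
    old_rates: tuple[float, ...]
    young_mean: float
    old_mean: float
    difference: float  # old_mean - young_mean, full precision
    passes: bool
    yeast_position: Optional[int] = None

    def __post_init__(self) -> None:
        if abs(self.difference - (self.old_mean - self.young_mean)) > 1e-12:
            raise ValueError("difference must equal old_mean - young_mean")


@dataclass(frozen=True)
class WindowSum:
    """Summed above-threshold mutation rate in one tiling window."""

    start: int  # 1-based first position of the window
    width: int  # nominal window width in bp
    n_positions: int  # actual positions covered (< width in a final partial window)
    summed_rate: float

    def __post_init__(self) -> None:
        if self.summed_rate < 0:
            raise ValueError(f"summed_rate must be >= 0, got {self.summed_rate}")

    @property
    def partial(self) -> bool:
        return self.n_positions < self.width


@dataclass(frozen=True)
class Fragment:
    """One restriction fragment, 1-based inclusive coordinates."""

    start: int
    end: int
    overlaps_probe: bool

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DigestResult:
    """Fragments from an in-silico digest of one unit."""

    unit_length: int
    enzymes: tuple[str, ...]
    blocked_sites: tuple[int, ...]
    fragments: tuple[Fragment, ...]

    def __post_init__(self) -> None:
        total = sum(f.length for f in self.fragments)
        if total != self.unit_length:
            raise ValueError(
                f"fragment lengths sum to {total}, expected unit_length {self.unit_length}"
            )
        prev_end = 0
        for f in self.fragments:
            if f.start != prev_end + 1:
                raise ValueError("fragments must be disjoint, ordered, and tiling")
            prev_end = f.end


@dataclass(frozen=True)
class LaneQuant:
    """Quantified band intensities for one gel lane."""

    label: str
    bands: dict[str, float]

    def __post_init__(self) -> None:
        for name, value in self.bands.items():
            if value < 0:
                raise ValueError(f"band {name!r} intensity must be >= 0, got {value}")


@dataclass(frozen=True)
class ExpressionMeasurement:
    """One RT-qPCR measurement."""

    sample_id: str
    target: str
    cq: float
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        if self.cq <= 0:
            raise ValueError(f"Cq must be > 0, got {self.cq}")
        if not 1.0 < self.efficiency <= 2.2:
            raise ValueError(f"efficiency must be in (1, 2.2], got {self.efficiency}")


@dataclass(frozen=True)
class SurvivalCurve:
    """Chronological-life-span survival, normalized to the day-3 CFU count."""

    days: tuple[int, ...]
    cfu: tuple[int, ...]
    survival: tuple[float, ...]

    def __post_init__(self) -> None:
        if 3 not in self.days:
            raise ValueError("day 3 must be present (normalization anchor)")
        if abs(self.survival[self.days.index(3)] - 1.0) > 1e-12:
            raise ValueError("survival at day 3 must be 1.0")

    @property
    def exceeds_one(self) -> tuple[int, ...]:
        """Days where the culture grew past its day-3 CFU count (flagged, not clipped)."""
        return tuple(d for d, s in zip(self.days, self.survival) if s > 1.0)
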
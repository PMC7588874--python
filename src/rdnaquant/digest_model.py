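"""In-silico restriction digestion and Southern-style band quantification.

A population of repeat units is digested with a set of enzymes; copies
carrying a methylated recognition site are protected from the
methylation-sensitive enzyme (SacII).  Band intensity is proportional to
the number of probe-hybridizing copies (one short probe, one hybridization
event per fragment — intensity does not scale with fragment length), and
lanes are normalized by a single-copy gene (SWI5, two copies per diploid
cell).  Three statistics come out of the lanes: relative copy number
(bands/SWI5 scaled to the young mean), the SacII undigested-band
methylation ratio, and the psoralen active/inactive transcription ratio.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np

from .models import (
    CellCopyProfile,
    DigestResult,
    Fragment,
    LaneQuant,
    RDNAUnitModel,
)

__all__ = [
    "SWI5_COPIES_PER_CELL",
    "band_label",
    "band_profile",
    "digest_unit",
    "methylation_undigested_ratio",
    "probe_fragments",
    "psoralen_active_ratio",
    "psoralen_intensities",
    "relative_copy_number_southern",
]

#: The loading-control gene is single-copy: two alleles per diploid cell.
SWI5_COPIES_PER_CELL = 2.0

#: Band label of the loading control in lane quantifications.
SWI5_BAND = "SWI5"


def digest_unit(
    unit: RDNAUnitModel,
    enzymes: Iterable[str],
    methylated_sites: Iterable[int] = (),
) -> DigestResult:
    """Cut one linear unit with the given enzymes.

    Every matching site cuts immediately before its position, except
    methylation-sensitive sites whose positions appear in
    ``methylated_sites`` (blocked).  The polymorphic BamHI-2 site cuts only
    when the unit carries it (``unit.bamhi2_position`` set).
    """
    enzymes = tuple(enzymes)
    blocked = frozenset(int(p) for p in methylated_sites)
    unknown = set(enzymes) - set(unit.enzymes)
    if unknown:
        raise ValueError(f"unknown enzyme(s) {sorted(unknown)}; unit has {sorted(unit.enzymes)}")
    cuts = []
    for site in unit.sites:
        if site.enzyme not in enzymes:
            continue
        if site.methylation_sensitive and site.position in blocked:
            continue
        if site.position > 1:  # a cut before position 1 is a no-op on a linear unit
            cuts.append(site.position)
    if unit.bamhi2_position is not None and "BamHI" in enzymes and unit.bamhi2_position > 1:
        cuts.append(unit.bamhi2_position)
    cuts = sorted(set(cuts))
    bounds = [1, *cuts, unit.unit_length + 1]
    p_start, p_end = unit.probe_interval
    fragments = tuple(
        Fragment(
            start=bounds[i],
            end=bounds[i + 1] - 1,
            overlaps_probe=not (bounds[i + 1] - 1 < p_start or bounds[i] > p_end),
        )
        for i in range(len(bounds) - 1)
    )
    return DigestResult(
        unit_length=unit.unit_length,
        enzymes=enzymes,
        blocked_sites=tuple(sorted(blocked)),
        fragments=fragments,
    )


def probe_fragments(result: DigestResult) -> list[Fragment]:
    """Fragments the Southern probe hybridizes to."""
    return [f for f in result.fragments if f.overlaps_probe]


def band_label(length_bp: int) -> str:
    """Gel band label from a fragment length, e.g. 4000 -> '4.0kb'."""
    return f"{length_bp / 1000:.1f}kb"


def band_profile(
    cells: Sequence[CellCopyProfile],
    unit: RDNAUnitModel,
    enzymes: Iterable[str],
    lane_label: str = "",
    exposure: float = 1.0,
) -> LaneQuant:
    """Expected band intensities for a lane loaded with these cells.

    Each copy contributes to the band of the probe fragment its state
    produces: with/without BamHI-2 according to the cell's
    ``bamhi2_fraction`` and, when SacII is applied, protected or cut
    according to ``methylated_fraction`` (states independent).  rDNA band
    intensity is the expected number of contributing copies scaled by one
    exposure constant; SWI5 is two copies per cell, unscaled.
    """
    enzymes = tuple(enzymes)
    sacii_applied = "SacII" in enzymes
    sacii_positions = [
        s.position for s in unit.sites if s.enzyme == "SacII" and s.methylation_sensitive
    ]

    # Probe-band labels for each (bamhi2, methylated) copy class.
    class_labels: dict[tuple[bool, bool], list[str]] = {}
    for has_b2 in (False, True):
        u = unit.with_bamhi2(unit.bamhi2_position or _default_bamhi2(unit)) if has_b2 else unit.without_bamhi2()
        for methylated in (False, True):
            blocked = sacii_positions if (sacii_applied and methylated) else ()
            result = digest_unit(u, enzymes, blocked)
            class_labels[(has_b2, methylated)] = [
                band_label(f.length) for f in probe_fragments(result)
            ]

    bands: dict[str, float] = {}
    for cell in cells:
        for has_b2 in (False, True):
            w_b2 = cell.bamhi2_fraction if has_b2 else 1.0 - cell.bamhi2_fraction
            if w_b2 == 0.0:
                continue
            if sacii_applied:
                weights = {
                    True: cell.methylated_fraction,
                    False: 1.0 - cell.methylated_fraction,
                }
            else:
                weights = {False: 1.0}
            for methylated, w_m in weights.items():
                if w_m == 0.0:
                    continue
                for label in class_labels[(has_b2, methylated)]:
                    bands[label] = bands.get(label, 0.0) + cell.copy_number * w_b2 * w_m
    bands = {k: v * exposure for k, v in bands.items()}
    bands[SWI5_BAND] = SWI5_COPIES_PER_CELL * len(cells)
    return LaneQuant(label=lane_label, bands=bands)


def _default_bamhi2(unit: RDNAUnitModel) -> int:
    """Fallback BamHI-2 placement when a unit lacking the site is profiled.

    The site splits the probe-detected BamHI-NdeI fragment at 2,400 bp from
    its BamHI end, matching the observed 4.0 -> 2.4 + 1.6 kb band split.
    """
    bamhi = [s.position for s in unit.sites if s.enzyme == "BamHI"]
    if not bamhi:
        raise ValueError("unit has no BamHI site; cannot place BamHI-2")
    return min(bamhi) + 2400


def relative_copy_number_southern(
    lanes: Mapping[str, LaneQuant],
    young_ids: Sequence[str],
    band_labels: Sequence[str] = ("4.0kb", "2.4kb"),
) -> dict[str, dict[str, float]]:
    """Per-sample band/SWI5 values scaled to the young-group mean.

    Returns ``{band: {sample: relative value}}``; the mean over the young
    samples is exactly 1 for each band by construction.
    """
    if not young_ids:
        raise ValueError("young_ids must be non-empty")
    missing = [s for s in young_ids if s not in lanes]
    if missing:
        raise ValueError(f"young sample(s) {missing} not among the lanes")
    norm: dict[str, dict[str, float]] = {}
    for band in band_labels:
        per_sample = {}
        for sample, lane in lanes.items():
            swi5 = lane.bands.get(SWI5_BAND, 0.0)
            if swi5 <= 0:
                raise ValueError(f"lane {sample!r} has no SWI5 signal")
            per_sample[sample] = lane.bands.get(band, 0.0) / swi5
        young_mean = float(np.mean([per_sample[s] for s in young_ids]))
        if young_mean == 0.0:
            raise ValueError(f"young mean for band {band!r} is zero; cannot normalize")
        norm[band] = {s: v / young_mean for s, v in per_sample.items()}
    return norm


def methylation_undigested_ratio(
    plus_lane: LaneQuant,
    minus_lane: LaneQuant,
    band_labels: Sequence[str] = ("4.0kb", "2.4kb"),
) -> dict[str, float]:
    """Fraction of copies protected from SacII, per band.

    ratio = (band/SWI5 in the SacII+ lane) / (band/SWI5 in the SacII- lane);
    1.0 means fully methylated (nothing digested), 0 fully unmethylated.
    """
    out = {}
    for band in band_labels:
        swi5_p = plus_lane.bands.get(SWI5_BAND, 0.0)
        swi5_m = minus_lane.bands.get(SWI5_BAND, 0.0)
        if swi5_p <= 0 or swi5_m <= 0:
            raise ValueError("both lanes need SWI5 signal > 0")
        minus_band = minus_lane.bands.get(band, 0.0)
        if minus_band <= 0:
            raise ValueError(f"band {band!r} absent from the SacII- lane")
        out[band] = (plus_lane.bands.get(band, 0.0) / swi5_p) / (minus_band / swi5_m)
    return out


def psoralen_intensities(cells: Sequence[CellCopyProfile]) -> tuple[float, float]:
    """(active, inactive) band intensities implied by per-cell active fractions."""
    active = sum(c.copy_number * c.active_fraction for c in cells)
    inactive = sum(c.copy_number * (1.0 - c.active_fraction) for c in cells)
    return float(active), float(inactive)


def psoralen_active_ratio(active_intensity: float, inactive_intensity: float) -> float:
    """Ratio of transcriptionally active to inactive rDNA copies.

    Driven from a uniform per-copy active fraction a, the expected ratio is
    a / (1 - a).
    """
    if inactive_intensity <= 0:
        raise ValueError("inactive intensity must be > 0")
    return active_intensity / inactive_intensity
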
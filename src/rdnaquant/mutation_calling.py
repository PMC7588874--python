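"""Per-position mutation-rate tracks and age-differential site calling.

The "mutation rate" here is a variant-copy frequency across the repeat
array: the fraction of reads at a position that differ from the reference
(substitutions, insertions and deletions pooled).  Sites where the rate
exceeds 0.9 in any sample are fixed differences from the reference, not
somatic variation, and are excluded throughout.  The artifact threshold for
calling is learned from a single-copy control locus: the maximum rate the
PCR/sequencing error process produced where no true variation is expected.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .models import (
    PILEUP_COLUMNS,
    AgeDifferentialCall,
    MutationRateTrack,
    Pileup,
    WindowSum,
)

__all__ = [
    "FIXED_DIFFERENCE_RATE",
    "MOUSE_TO_YEAST_28S",
    "call_age_differential_sites",
    "control_gene_threshold",
    "hotspot_window_sums",
    "merge_window_sums",
    "mutation_rate_track",
    "pileup_from_alignments",
    "restriction_site_variant_summary",
]

#: Rates above this are fixed reference differences, not somatic variation.
FIXED_DIFFERENCE_RATE = 0.9

#: Conserved-position lookup from the mouse 28S local coordinate to the
#: budding-yeast 25S coordinate, for the two conserved old-specific sites.
MOUSE_TO_YEAST_28S: dict[int, int] = {4614: 3295, 3291: 2131}

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


def _load_reference(reference) -> dict[str, str]:
    """Accept a FASTA path or a mapping name -> sequence."""
    if isinstance(reference, Mapping):
        return {str(k): str(v).upper() for k, v in reference.items()}
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(reference), "fasta")}


def _empty_counts(length: int) -> np.ndarray:
    return np.zeros((length, len(PILEUP_COLUMNS)), dtype=np.int64)


def _pileup_from_sam(path, refs: dict[str, str], locus: Optional[str]) -> Pileup:
    import pysam

    with pysam.AlignmentFile(str(path), "r", check_sq=False) as af:
        reads = [r for r in af if not r.is_unmapped]
    if not reads:
        warnings.warn(f"no mapped reads in {path}; returning an empty pileup", stacklevel=3)
        name = locus if locus is not None else next(iter(refs))
        return Pileup(locus=name, ref=refs[name], counts=_empty_counts(len(refs[name])))
    names = {r.reference_name for r in reads}
    if locus is not None:
        if locus not in names and locus not in refs:
            raise ValueError(f"locus {locus!r} not present in alignments or reference")
        names = {locus}
    elif len(names) > 1:
        raise ValueError(f"multiple reference names {sorted(names)}; pass locus explicitly")
    name = next(iter(names))
    if name not in refs:
        raise ValueError(f"alignment reference {name!r} not found in the FASTA")
    ref = refs[name]
    counts = _empty_counts(len(ref))
    for read in reads:
        if read.reference_name != name:
            continue
        seq = read.query_sequence or ""
        rpos = read.reference_start  # 0-based
        qpos = 0
        for op, ln in read.cigartuples or ():
            if op in (0, 7, 8):  # aligned
                for i in range(ln):
                    base = seq[qpos + i]
                    if base in _BASE_INDEX and rpos + i < len(ref):
                        counts[rpos + i, _BASE_INDEX[base]] += 1
                rpos += ln
                qpos += ln
            elif op == 1:  # insertion: counted at the preceding reference position
                if rpos > 0:
                    counts[rpos - 1, 4] += 1
                qpos += ln
            elif op == 2:  # deletion spans the reference positions
                counts[rpos : rpos + ln, 5] += 1
                rpos += ln
            elif op == 4:  # soft clip: ignored
                qpos += ln
            elif op == 3:  # reference skip
                rpos += ln
            # hard clip (5) and pad (6): nothing to do
    return Pileup(locus=name, ref=ref, counts=counts)


def _pileup_from_tsv(path, refs: dict[str, str], locus: Optional[str]) -> Pileup:
    """Position/base TSV: one row per aligned base.

    Columns ``position`` (1-based) and ``base``; ``base`` is A/C/G/T, ``-``
    for a deleted position, or ``+``-prefixed for an insertion recorded at
    the reference position preceding the inserted bases (the same
    convention as the SAM reader).  An optional ``locus`` column selects the
    reference sequence.
    """
    df = pd.read_csv(path, sep="\t", dtype={"base": str})
    if locus is None:
        if "locus" in df.columns and df["locus"].nunique() == 1:
            locus = str(df["locus"].iloc[0])
        elif len(refs) == 1:
            locus = next(iter(refs))
        else:
            raise ValueError("ambiguous locus; pass locus explicitly")
    if locus not in refs:
        raise ValueError(f"locus {locus!r} not found in the reference")
    ref = refs[locus]
    counts = _empty_counts(len(ref))
    if df.empty:
        warnings.warn(f"no rows in {path}; returning an empty pileup", stacklevel=3)
        return Pileup(locus=locus, ref=ref, counts=counts)
    for row in df.itertuples():
        pos = int(row.position) - 1
        if not 0 <= pos < len(ref):
            raise ValueError(f"position {row.position} outside reference [1, {len(ref)}]")
        base = row.base
        if base == "-":
            counts[pos, 5] += 1
        elif base.startswith("+"):
            counts[pos, 4] += 1
        elif base in _BASE_INDEX:
            counts[pos, _BASE_INDEX[base]] += 1
        else:
            raise ValueError(f"unrecognized base entry {base!r}")
    return Pileup(locus=locus, ref=ref, counts=counts)


def pileup_from_alignments(
    alignments, reference, locus: Optional[str] = None
) -> Pileup:
    """Accumulate a per-position pileup from SAM records or a position/base TSV.

    Soft-clipped bases are ignored; an insertion is counted once at the
    reference position preceding the inserted bases; a deletion is counted
    at every deleted position.  The two encodings of the same reads yield
    identical pileups.
    """
    refs = _load_reference(reference)
    path = Path(str(alignments))
    if path.suffix.lower() == ".sam":
        return _pileup_from_sam(path, refs, locus)
    return _pileup_from_tsv(path, refs, locus)


def mutation_rate_track(
    pileup: Pileup, sample_id: str = "", age_group: str = "young"
) -> MutationRateTrack:
    """Pooled per-position mutation rate from a pileup.

    rate = (non-reference bases + insertions + deletions) / depth, clipped
    at 1; zero-depth positions are masked (NaN), never reported as zero.
    Per-class rates are retained alongside the pooled rate.
    """
    depth = pileup.depth.astype(float)
    ref_idx = np.array([_BASE_INDEX.get(b, -1) for b in pileup.ref])
    rows = np.arange(len(pileup))
    ref_count = np.where(
        ref_idx >= 0, pileup.counts[rows, np.clip(ref_idx, 0, 3)], 0
    ).astype(float)
    ins = pileup.counts[:, 4].astype(float)
    dele = pileup.counts[:, 5].astype(float)
    sub = depth - ref_count - dele  # non-reference base calls
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.where(depth > 0, np.minimum(1.0, (sub + ins + dele) / depth), np.nan)
        sub_r = np.where(depth > 0, sub / depth, np.nan)
        ins_r = np.where(depth > 0, ins / depth, np.nan)
        del_r = np.where(depth > 0, dele / depth, np.nan)
    return MutationRateTrack(
        sample_id=sample_id,
        age_group=age_group,
        locus=pileup.locus,
        rates=rates,
        depth=pileup.depth.copy(),
        substitution_rates=sub_r,
        insertion_rates=ins_r,
        deletion_rates=del_r,
    )


def control_gene_threshold(control_tracks: Sequence[MutationRateTrack]) -> float:
    """Artifact threshold: maximum control-locus rate over positions and samples.

    Rates above :data:`FIXED_DIFFERENCE_RATE` are fixed reference
    differences and are excluded before taking the maximum.
    """
    if not control_tracks:
        raise ValueError("need at least one control track")
    pool = np.concatenate([t.rates for t in control_tracks])
    pool = pool[~np.isnan(pool)]
    pool = pool[pool <= FIXED_DIFFERENCE_RATE]
    if pool.size == 0:
        raise ValueError("control locus has no usable positions (all masked or fixed)")
    return float(pool.max())


def call_age_differential_sites(
    young: Sequence[MutationRateTrack],
    old: Sequence[MutationRateTrack],
    threshold: float,
    require_separation: bool = True,
    min_samples_per_group: int = 2,
) -> list[AgeDifferentialCall]:
    """Candidate age-differential sites, sorted by |difference| descending.

    Positions where any sample's rate exceeds 0.9 (fixed reference
    differences) or is masked are excluded.  A candidate has
    |old_mean - young_mean| > threshold; it *passes* when, additionally,
    the two groups are separated: every sample of the higher-mean group
    exceeds every sample of the lower-mean group.  Separation can be turned
    off to reproduce a means-only screen.
    """
    if len(young) == 0 or len(old) == 0:
        raise ValueError("both age groups need at least one track")
    if len(young) < min_samples_per_group or len(old) < min_samples_per_group:
        warnings.warn(
            f"fewer than {min_samples_per_group} samples in a group; "
            "group means are poorly supported",
            stacklevel=2,
        )
    lengths = {len(t) for t in [*young, *old]}
    if len(lengths) != 1:
        raise ValueError(f"tracks have differing lengths: {sorted(lengths)}")
    y = np.vstack([t.rates for t in young])
    o = np.vstack([t.rates for t in old])
    locus = young[0].locus

    usable = ~(np.isnan(y).any(axis=0) | np.isnan(o).any(axis=0))
    usable &= (y <= FIXED_DIFFERENCE_RATE).all(axis=0) & (o <= FIXED_DIFFERENCE_RATE).all(axis=0)
    y_mean = y.mean(axis=0)
    o_mean = o.mean(axis=0)
    diff = o_mean - y_mean
    candidate = usable & (np.abs(diff) > threshold)

    calls = []
    for pos0 in np.nonzero(candidate)[0]:
        y_rates = y[:, pos0]
        o_rates = o[:, pos0]
        if diff[pos0] >= 0:
            separated = o_rates.min() > y_rates.max()
        else:
            separated = y_rates.min() > o_rates.max()
        passes = bool(separated) if require_separation else True
        position = int(pos0) + 1
        calls.append(
            AgeDifferentialCall(
                position=position,
                young_rates=tuple(float(v) for v in y_rates),
                old_rates=tuple(float(v) for v in o_rates),
                young_mean=float(y_mean[pos0]),
                old_mean=float(o_mean[pos0]),
                difference=float(o_mean[pos0]) - float(y_mean[pos0]),
                passes=passes,
                yeast_position=MOUSE_TO_YEAST_28S.get(position) if locus == "28S" else None,
            )
        )
    calls.sort(key=lambda c: abs(c.difference), reverse=True)
    return calls


def hotspot_window_sums(
    track: MutationRateTrack, threshold: float, width: int = 20
) -> list[WindowSum]:
    """Above-threshold rates summed in non-overlapping windows from position 1.

    Only rates in (threshold, 0.9] contribute; masked positions contribute
    nothing.  The final partial window is kept and labeled via its
    ``n_positions``.
    """
    if width < 1:
        raise ValueError(f"width must be >= 1, got {width}")
    rates = track.rates
    contrib = np.where(
        np.isnan(rates) | (rates <= threshold) | (rates > FIXED_DIFFERENCE_RATE),
        0.0,
        rates,
    )
    out = []
    for start0 in range(0, len(rates), width):
        chunk = contrib[start0 : start0 + width]
        out.append(
            WindowSum(
                start=start0 + 1,
                width=width,
                n_positions=len(chunk),
                summed_rate=float(chunk.sum()),
            )
        )
    return out


def merge_window_sums(*window_lists: Sequence[WindowSum]) -> list[WindowSum]:
    """Add window sums position-wise across tracks of the same tiling."""
    first = window_lists[0]
    for other in window_lists[1:]:
        if [(w.start, w.width, w.n_positions) for w in other] != [
            (w.start, w.width, w.n_positions) for w in first
        ]:
            raise ValueError("window tilings differ; cannot merge")
    return [
        WindowSum(
            start=w.start,
            width=w.width,
            n_positions=w.n_positions,
            summed_rate=float(sum(lst[i].summed_rate for lst in window_lists)),
        )
        for i, w in enumerate(first)
    ]


def restriction_site_variant_summary(
    tracks_by_sample: Mapping[str, MutationRateTrack],
    site_positions: Sequence[int],
) -> tuple[dict[str, float], dict[str, float]]:
    """Summed variant rates over a restriction site, per sample and per group.

    Returns ``(per_sample_sums, per_group_averages)`` where groups are the
    tracks' age groups.  A site position missing from a track (out of range
    or masked) is an error naming the position.
    """
    per_sample: dict[str, float] = {}
    groups: dict[str, list[float]] = {}
    for sample_id, track in tracks_by_sample.items():
        total = 0.0
        for pos in site_positions:
            if not 1 <= pos <= len(track):
                raise ValueError(
                    f"site position {pos} missing from track of sample {sample_id!r}"
                )
            rate = track.rates[pos - 1]
            if np.isnan(rate):
                raise ValueError(
                    f"site position {pos} is masked (zero depth) in sample {sample_id!r}"
                )
            total += float(rate)
        per_sample[sample_id] = total
        groups.setdefault(track.age_group, []).append(total)
    per_group = {g: float(np.mean(v)) for g, v in groups.items()}
    return per_sample, per_group
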
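"""Seeded generators for synthetic cohorts and assay readouts.

Everything downstream of the wet lab is driven by five generators:

* :func:`generate_cohort` draws per-cell copy numbers and per-copy state
  fractions for young/old mice of one strain;
* :func:`simulate_droplet_assay` partitions template copies into droplets
  (the Poisson end-point the ddPCR inversion assumes);
* :func:`simulate_qpcr_cq` produces quantification cycles from a standard
  curve;
* :func:`simulate_amplicon_pileup` produces per-position base counts for a
  deep-sequenced amplicon with a PCR/sequencing error floor and planted
  per-copy variants;
* :func:`simulate_wgs_readcounts` draws the rDNA read fraction of a
  whole-genome sequencing run.

All randomness flows from explicit integer seeds (or generators) so every
stage is bit-reproducible; the pipeline derives per-stage substreams from
one root seed via :func:`substream_rng`.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .models import (
    AGE_GROUPS,
    PILEUP_COLUMNS,
    CellCopyProfile,
    CohortConfig,
    DropletCounts,
    MouseSample,
    Pileup,
    RDNAUnitModel,
    RestrictionSite,
    StandardCurve,
    VariantDef,
)

__all__ = [
    "DEFAULT_LOCUS_LENGTHS",
    "NO_AMPLIFICATION",
    "build_unit_model",
    "default_unit_model",
    "default_variants",
    "generate_cohort",
    "read_cohort_tsv",
    "read_config_toml",
    "reference_sequence",
    "simulate_amplicon_pileup",
    "simulate_droplet_assay",
    "simulate_qpcr_cq",
    "simulate_wgs_readcounts",
    "substream_rng",
    "write_cohort_tsv",
    "write_config_toml",
    "write_pileup_tsv",
    "write_site_table",
    "write_unit_fasta",
]

SeedLike = Union[int, np.random.Generator, np.random.SeedSequence, None]

#: Sentinel returned by the qPCR simulator when there is no template.
NO_AMPLIFICATION = None

#: Amplicon lengths (bp) of the sequenced loci, on their local coordinates.
#: The 28S amplicon coordinate extends past the mature 28S 3' end so that
#: the polymorphic BamHI site at 5050-5055 lies inside it.
DEFAULT_LOCUS_LENGTHS: dict[str, int] = {
    "18S": 1870,
    "5.8S": 157,
    "28S": 5100,
    "control": 460,
}

# Default unit geometry: a ~43 kb repeat whose BamHI-1/NdeI double digest
# releases a 4,000 bp probe-bearing fragment; the polymorphic BamHI-2 site
# splits it into 2,400 bp (probe side) + 1,600 bp.  A single representative
# methylation-sensitive SacII site sits inside the probe fragment.
_UNIT_LENGTH = 43_000
_BAMHI1 = 30_001
_NDEI = 34_001
_SACII = 31_501
_BAMHI2 = 32_401
_PROBE = (30_501, 31_000)

_REF_SEED = 20_200_964  # stable reference-sequence seed, not user-tunable


def _as_rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def substream_rng(root_seed: int, *key: int) -> np.random.Generator:
    """Derive a named, independent random substream from one root seed.

    The stream is ``SeedSequence(root_seed, spawn_key=key)``; re-running a
    single stage with the same root seed therefore reproduces its draws
    regardless of what other stages consumed.
    """
    ss = np.random.SeedSequence(entropy=int(root_seed), spawn_key=tuple(int(k) for k in key))
    return np.random.default_rng(ss)


def default_variants(strain: str = "BALB/cA-like") -> tuple[VariantDef, ...]:
    """Per-copy 28S variants planted by default.

    Frequencies are the group-mean variant-copy fractions observed for the
    BALB/cA-like configuration: two old-specific substitutions (positions
    4614 and 3291), one young-high site (3094), and the three substitutions
    that convert the internal BamHI site GGATCC to GGGGTC (positions
    5052-5054).  The C57BL/6-like configuration carries the BamHI-site
    variant without an age trend and no old-specific sites.
    """
    if strain.startswith("C57"):
        return (
            VariantDef(5052, "A", "G", 0.235, 0.210),
            VariantDef(5053, "T", "G", 0.100, 0.085),
            VariantDef(5054, "C", "T", 0.095, 0.085),
        )
    return (
        VariantDef(4614, "A", "G", 0.001, 0.419),
        VariantDef(3291, "A", "G", 0.001, 0.035),
        VariantDef(3094, "C", "T", 0.037, 0.008),
        VariantDef(5052, "A", "G", 0.250, 0.335),
        VariantDef(5053, "T", "G", 0.000, 0.175),
        VariantDef(5054, "C", "T", 0.000, 0.175),
    )


def build_unit_model(config: Mapping) -> RDNAUnitModel:
    """Validate a unit-model description and return the model.

    ``config`` maps field names to values: ``unit_length``, ``sites`` (an
    iterable of ``(enzyme, position, methylation_sensitive)`` triples or
    :class:`RestrictionSite`), ``probe_interval``, optional
    ``bamhi2_position`` and ``variants``.
    """
    sites = []
    for s in config.get("sites", ()):
        if isinstance(s, RestrictionSite):
            sites.append(s)
        else:
            enzyme, position, *rest = s
            sites.append(RestrictionSite(str(enzyme), int(position), bool(rest[0]) if rest else False))
    variants = []
    for v in config.get("variants", ()):
        if isinstance(v, VariantDef):
            variants.append(v)
        else:
            variants.append(VariantDef(*v))
    return RDNAUnitModel(
        unit_length=int(config["unit_length"]),
        sites=tuple(sites),
        probe_interval=tuple(config["probe_interval"]),
        bamhi2_position=config.get("bamhi2_position"),
        variants=tuple(variants),
    )


def default_unit_model(
    include_bamhi2: bool = False, strain: str = "BALB/cA-like"
) -> RDNAUnitModel:
    """The packaged unit fixture (see module comment for the geometry)."""
    return RDNAUnitModel(
        unit_length=_UNIT_LENGTH,
        sites=(
            RestrictionSite("BamHI", _BAMHI1),
            RestrictionSite("NdeI", _NDEI),
            RestrictionSite("SacII", _SACII, methylation_sensitive=True),
        ),
        probe_interval=_PROBE,
        bamhi2_position=_BAMHI2 if include_bamhi2 else None,
        variants=default_variants(strain),
    )


# ---------------------------------------------------------------------------
# cohort generation


def _lognormal_copies(
    rng: np.random.Generator, mean: float, cv: float, n: int
) -> np.ndarray:
    """Integer copy numbers from a moment-matched log-normal.

    sigma^2 = ln(1 + cv^2), mu = ln(mean) - sigma^2/2 gives E[X] = mean and
    SD[X]/E[X] = cv; draws are rounded half-up to integers.
    """
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    draws = rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n)
    return np.floor(draws + 0.5).astype(int)


def _beta_around(
    rng: np.random.Generator, f: float, n: int, concentration: float = 150.0
) -> np.ndarray:
    """Per-cell fractions centered on a group fraction f (Beta, mean f)."""
    if f <= 0.0:
        return np.zeros(n)
    if f >= 1.0:
        return np.ones(n)
    return rng.beta(f * concentration, (1.0 - f) * concentration, size=n)


def generate_cohort(config: CohortConfig, seed: SeedLike = None) -> list[MouseSample]:
    """Draw young and old mice with per-cell copy numbers and state fractions.

    Copy numbers are log-normal (moment-matched to the configured mean and
    CV, rounded to integers); per-cell state fractions are Beta-distributed
    around the configured group fractions.  A fixed seed reproduces the
    cohort exactly.  ``seed`` defaults to ``config.seed``.
    """
    rng = _as_rng(config.seed if seed is None else seed)
    tag = "B" if not config.strain.startswith("C57") else "C"
    samples: list[MouseSample] = []
    for age_group in AGE_GROUPS:
        mean = config.mean_copies_young if age_group == "young" else config.mean_copies_old
        cv = config.cv_young if age_group == "young" else config.cv_old
        fractions = config.group_fractions(age_group)
        for i in range(config.n_mice):
            copies = _lognormal_copies(rng, mean, cv, config.cells_per_mouse)
            cell_fracs = {
                name: _beta_around(rng, value, config.cells_per_mouse)
                for name, value in fractions.items()
            }
            mouse_id = f"{tag}-{age_group}-{i + 1}"
            cells = tuple(
                CellCopyProfile(
                    cell_id=f"{mouse_id}-c{j + 1}",
                    copy_number=int(copies[j]),
                    bamhi2_fraction=float(cell_fracs["bamhi2_fraction"][j]),
                    methylated_fraction=float(cell_fracs["methylated_fraction"][j]),
                    active_fraction=float(cell_fracs["active_fraction"][j]),
                )
                for j in range(config.cells_per_mouse)
            )
            samples.append(
                MouseSample(
                    mouse_id=mouse_id,
                    strain=config.strain,
                    age_group=age_group,
                    sex="m" if i % 2 == 0 else "f",
                    cells=cells,
                )
            )
    return samples


# ---------------------------------------------------------------------------
# assay simulators


def simulate_droplet_assay(
    total_copies_in_reaction: int, n_droplets: int, seed: SeedLike = None
) -> DropletCounts:
    """Partition template copies uniformly at random into droplets.

    A droplet is positive if it received at least one copy.  This is the
    exact occupancy process whose positive fraction converges to
    1 - exp(-copies/droplets).
    """
    if n_droplets <= 0:
        raise ValueError(f"n_droplets must be > 0, got {n_droplets}")
    if total_copies_in_reaction < 0:
        raise ValueError(f"total copies must be >= 0, got {total_copies_in_reaction}")
    rng = _as_rng(seed)
    if total_copies_in_reaction == 0:
        return DropletCounts(n_total=n_droplets, n_positive=0)
    occupancy = rng.multinomial(
        int(total_copies_in_reaction), np.full(n_droplets, 1.0 / n_droplets)
    )
    return DropletCounts(n_total=n_droplets, n_positive=int((occupancy > 0).sum()))


def simulate_qpcr_cq(
    copies: float,
    curve: StandardCurve,
    noise_sd: float = 0.0,
    seed: SeedLike = None,
) -> Optional[float]:
    """Cq for a reaction with the given template copies.

    Returns :data:`NO_AMPLIFICATION` (``None``) when ``copies`` is zero —
    a failed reaction is a sentinel, not a number.
    """
    if copies < 0:
        raise ValueError(f"copies must be >= 0, got {copies}")
    if copies == 0:
        return NO_AMPLIFICATION
    cq = curve.predict_cq(copies)
    if noise_sd > 0.0:
        cq += float(_as_rng(seed).normal(0.0, noise_sd))
    return float(cq)


def reference_sequence(unit: RDNAUnitModel, locus: str, length: Optional[int] = None) -> str:
    """Deterministic synthetic reference for one sequenced locus.

    The sequence is a fixed pseudo-random draw keyed on the locus name, with
    the unit model's variant reference bases written in at their positions,
    so pileup simulation and reference-aware rate computation agree.
    """
    if length is None:
        try:
            length = DEFAULT_LOCUS_LENGTHS[locus]
        except KeyError:
            raise ValueError(
                f"no default length for locus {locus!r}; pass length explicitly"
            ) from None
    key = [_REF_SEED] + [ord(ch) for ch in locus]
    rng = np.random.default_rng(np.random.SeedSequence(key))
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=length)
    if locus == "28S":
        for v in unit.variants:
            if v.position <= length:
                seq[v.position - 1] = v.ref_base
    return "".join(seq)


def simulate_amplicon_pileup(
    unit: RDNAUnitModel,
    age_group: str,
    depth: int,
    error_floor: float,
    seed: SeedLike = None,
    locus: str = "28S",
    length: Optional[int] = None,
) -> Pileup:
    """Per-position base counts for one deep-sequenced amplicon.

    At each position, variant-carrying reads are Binomial(depth, f) with f
    the planted per-copy frequency for ``age_group`` (zero off-variant), and
    the remaining reads err with probability ``error_floor``, uniformly over
    the three non-reference bases.  The total non-reference rate is then
    f + (1 - f) * error_floor in expectation: a read is non-reference if it
    carries the variant or an error struck a reference copy.
    """
    if depth <= 0:
        raise ValueError(f"depth must be > 0, got {depth}")
    if not 0.0 <= error_floor <= 0.25:
        raise ValueError(f"error_floor must be in [0, 0.25], got {error_floor}")
    if age_group not in AGE_GROUPS:
        raise ValueError(f"age_group must be one of {AGE_GROUPS}, got {age_group!r}")
    rng = _as_rng(seed)
    ref = reference_sequence(unit, locus, length)
    n = len(ref)
    base_index = {b: i for i, b in enumerate("ACGT")}
    ref_idx = np.array([base_index[b] for b in ref])

    freqs = np.zeros(n)
    alt_idx = np.full(n, -1)
    if locus == "28S":
        for v in unit.variants:
            if v.position <= n:
                freqs[v.position - 1] = v.frequency(age_group)
                alt_idx[v.position - 1] = base_index[v.alt_base]

    variant_reads = rng.binomial(depth, freqs)
    error_reads = rng.binomial(depth - variant_reads, error_floor)
    # split errors over the three non-reference bases by conditional binomials
    e1 = rng.binomial(error_reads, 1.0 / 3.0)
    e2 = rng.binomial(error_reads - e1, 0.5)
    e3 = error_reads - e1 - e2
    err_split = np.stack([e1, e2, e3], axis=1)

    counts = np.zeros((n, len(PILEUP_COLUMNS)), dtype=np.int64)
    non_ref = np.array([[b for b in range(4) if b != r] for r in ref_idx])
    rows = np.arange(n)
    counts[rows, ref_idx] = depth - variant_reads - error_reads
    for k in range(3):
        np.add.at(counts, (rows, non_ref[:, k]), err_split[:, k])
    has_var = alt_idx >= 0
    np.add.at(counts, (rows[has_var], alt_idx[has_var]), variant_reads[has_var])
    return Pileup(locus=locus, ref=ref, counts=counts)


def simulate_wgs_readcounts(
    copies_per_cell: int,
    unit_length: int,
    non_rdna_genome_length: float,
    total_reads: int,
    seed: SeedLike = None,
) -> tuple[int, int]:
    """(rdna_reads, total_mapped_reads) for a uniform-coverage WGS run.

    Reads fall in the rDNA array with probability
    p = copies * unit_length / (non_rdna_genome_length + copies * unit_length).
    """
    if unit_length <= 0 or non_rdna_genome_length <= 0 or total_reads <= 0:
        raise ValueError("lengths and read counts must be > 0")
    if copies_per_cell < 0:
        raise ValueError(f"copies_per_cell must be >= 0, got {copies_per_cell}")
    rdna_mass = copies_per_cell * unit_length
    p = rdna_mass / (non_rdna_genome_length + rdna_mass)
    rdna_reads = int(_as_rng(seed).binomial(total_reads, p))
    return rdna_reads, int(total_reads)


# ---------------------------------------------------------------------------
# on-disk formats (all plain text)


def write_unit_fasta(unit: RDNAUnitModel, path) -> None:
    """Write a synthetic unit sequence realizing the site coordinates.

    The sequence is pseudo-random with each enzyme's recognition motif
    planted so that its first base sits at the recorded site position.
    """
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    motifs = {"BamHI": "GGATCC", "NdeI": "CATATG", "SacII": "CCGCGG"}
    rng = np.random.default_rng(np.random.SeedSequence([_REF_SEED, unit.unit_length]))
    seq = rng.choice(np.array(list("ACGT")), size=unit.unit_length)
    positions = [(s.enzyme, s.position) for s in unit.sites]
    if unit.bamhi2_position is not None:
        positions.append(("BamHI", unit.bamhi2_position))
    for enzyme, pos in positions:
        motif = motifs.get(enzyme)
        if motif is None:
            continue
        end = min(pos - 1 + len(motif), unit.unit_length)
        seq[pos - 1 : end] = list(motif[: end - (pos - 1)])
    record = SeqRecord(
        Seq("".join(seq)),
        id="rDNA_unit",
        description=f"synthetic rDNA repeat unit, {unit.unit_length} bp, coordinates 1-based",
    )
    seqio_write([record], str(path), "fasta")


def write_site_table(unit: RDNAUnitModel, path) -> None:
    rows = [
        {"enzyme": s.enzyme, "position": s.position, "methylation_sensitive": s.methylation_sensitive}
        for s in unit.sites
    ]
    if unit.bamhi2_position is not None:
        rows.append({"enzyme": "BamHI", "position": unit.bamhi2_position, "methylation_sensitive": False})
    pd.DataFrame(rows).sort_values("position").to_csv(path, sep="\t", index=False)


def write_cohort_tsv(samples: Sequence[MouseSample], path) -> None:
    rows = []
    for s in samples:
        for c in s.cells:
            rows.append(
                {
                    "mouse_id": s.mouse_id,
                    "strain": s.strain,
                    "age_group": s.age_group,
                    "sex": s.sex,
                    "cell_id": c.cell_id,
                    "copy_number": c.copy_number,
                    "bamhi2_fraction": f"{c.bamhi2_fraction:.6f}",
                    "methylated_fraction": f"{c.methylated_fraction:.6f}",
                    "active_fraction": f"{c.active_fraction:.6f}",
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_cohort_tsv(path) -> list[MouseSample]:
    df = pd.read_csv(path, sep="\t")
    samples = []
    for (mouse_id, strain, age_group, sex), grp in df.groupby(
        ["mouse_id", "strain", "age_group", "sex"], sort=False
    ):
        cells = tuple(
            CellCopyProfile(
                cell_id=row.cell_id,
                copy_number=int(row.copy_number),
                bamhi2_fraction=float(row.bamhi2_fraction),
                methylated_fraction=float(row.methylated_fraction),
                active_fraction=float(row.active_fraction),
            )
            for row in grp.itertuples()
        )
        samples.append(MouseSample(mouse_id, strain, age_group, sex, cells))
    return samples


def write_pileup_tsv(pileup: Pileup, path) -> None:
    df = pd.DataFrame(pileup.counts, columns=list(PILEUP_COLUMNS))
    df.insert(0, "ref", list(pileup.ref))
    df.insert(0, "position", np.arange(1, len(pileup) + 1))
    df["depth"] = pileup.depth
    df.insert(0, "locus", pileup.locus)
    df.to_csv(path, sep="\t", index=False)


def write_config_toml(config: CohortConfig, path) -> None:
    """Serialize a cohort config as a flat [cohort] TOML table."""
    lines = ["[cohort]"]
    for name, value in vars(config).items():
        if isinstance(value, str):
            lines.append(f'{name} = "{value}"')
        elif isinstance(value, bool):
            lines.append(f"{name} = {str(value).lower()}")
        else:
            lines.append(f"{name} = {value}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_config_toml(path) -> CohortConfig:
    import tomllib

    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    table = data.get("cohort", data)
    valid = set(CohortConfig.__dataclass_fields__)
    unknown = set(table) - valid
    if unknown:
        raise ValueError(f"unknown cohort config fields: {sorted(unknown)}")
    return CohortConfig(**table)
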
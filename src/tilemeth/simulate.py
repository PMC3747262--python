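"""Synthetic MeDIP tiling-array studies with known ground truth.

The generator emulates the design of a two-group locus-wide methylation
study: a small case group (default 8 subjects) against a larger control
group (default 12), two sorted cell types per subject, three replicate
arrays per sample, and probes tiled at 100-bp spacing across ~100-kb gene
loci.  Differentially methylated regions (DMRs) of ~1 kb are planted as
additive log2 shifts in the case group, and plasma-phenotype values can be
linked linearly to the true methylation of a planted region.

Noise is additive Gaussian on the log2(bound/input) scale at three levels:
a per-subject biological deviation per probe, a per-array technical offset,
and per-measurement probe noise.  The input channel is log-normal around a
fixed brightness and the bound channel is derived from the simulated
log-ratio, so channels are strictly positive and the planted log-ratios are
exact in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidSpecError
from .io import AnnotationTrack, validate_probe_design

DEFAULT_CELL_TYPES = ("T_cell", "monocyte")


@dataclass(frozen=True)
class LocusSpec:
    """A tiled genomic locus: ``[start, start + length)`` on ``chrom``."""

    locus_id: str
    chrom: str
    start: int
    length: int


@dataclass(frozen=True)
class PlantedDMR:
    """A ground-truth differentially methylated region.

    ``effect`` is the log2 mean shift of group A relative to group B for
    every probe whose start falls in ``[start, end)`` (genomic coordinates).
    ``cell_types`` restricts the effect to those cell types (None = all).
    """

    locus_id: str
    start: int
    end: int
    effect: float
    label: str
    cell_types: tuple[str, ...] | None = None


@dataclass(frozen=True)
class PhenotypeLink:
    """A linear link from a planted region's true methylation to a phenotype.

    level = intercept + slope * (subject mean true methylation over the
    region) + N(0, noise_sd), in phenotype units (e.g. pg/ml).
    """

    region: str  # label of a PlantedDMR
    analyte: str
    slope: float
    intercept: float = 0.0
    noise_sd: float = 1.0
    cell_type: str | None = None  # default: first cell type of the spec


@dataclass
class SimulationSpec:
    """Full description of a synthetic study; defaults mirror the emulated design."""

    loci: tuple[LocusSpec, ...]
    n_group_a: int = 8
    n_group_b: int = 12
    n_replicates: int = 3
    probe_spacing: int = 100
    probe_length: int | None = None  # None: probes tile contiguously at the spacing
    probe_noise_sd: float = 0.3
    subject_sd: float = 0.3
    replicate_sd: float = 0.2
    planted_dmrs: tuple[PlantedDMR, ...] = ()
    phenotype_links: tuple[PhenotypeLink, ...] = ()
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    seed: int = 0

    def __post_init__(self) -> None:
        self.loci = tuple(self.loci)
        self.planted_dmrs = tuple(self.planted_dmrs)
        self.phenotype_links = tuple(self.phenotype_links)
        self.cell_types = tuple(self.cell_types)
        self.validate()

    def validate(self) -> None:
        if self.n_group_a < 1 or self.n_group_b < 1 or self.n_replicates < 1:
            raise InvalidSpecError("group sizes and replicate count must be positive")
        if self.probe_spacing <= 0 or (self.probe_length is not None and self.probe_length <= 0):
            raise InvalidSpecError("probe spacing and length must be positive")
        for sd in (self.probe_noise_sd, self.subject_sd, self.replicate_sd):
            if sd <= 0:
                raise InvalidSpecError("all noise SDs must be > 0")
        if not self.loci:
            raise InvalidSpecError("at least one locus required")
        by_id = {l.locus_id: l for l in self.loci}
        if len(by_id) != len(self.loci):
            raise InvalidSpecError("duplicate locus_id")
        for locus in self.loci:
            if locus.length < self.probe_spacing:
                raise InvalidSpecError(f"locus {locus.locus_id!r} shorter than probe spacing")
        labels = set()
        for dmr in self.planted_dmrs:
            if dmr.end <= dmr.start:
                raise InvalidSpecError(f"planted DMR {dmr.label!r}: end <= start")
            if dmr.effect == 0:
                raise InvalidSpecError(f"planted DMR {dmr.label!r}: effect must be nonzero")
            locus = by_id.get(dmr.locus_id)
            if locus is None:
                raise InvalidSpecError(f"planted DMR {dmr.label!r}: unknown locus {dmr.locus_id!r}")
            if dmr.start < locus.start or dmr.end > locus.start + locus.length:
                raise InvalidSpecError(f"planted DMR {dmr.label!r} outside locus {dmr.locus_id!r}")
            if dmr.label in labels:
                raise InvalidSpecError(f"duplicate DMR label {dmr.label!r}")
            labels.add(dmr.label)
        for link in self.phenotype_links:
            if link.noise_sd <= 0:
                raise InvalidSpecError(f"phenotype link {link.analyte!r}: noise_sd must be > 0")
            if link.region not in labels:
                raise InvalidSpecError(f"phenotype link references unknown region {link.region!r}")
            if link.cell_type is not None and link.cell_type not in self.cell_types:
                raise InvalidSpecError(f"phenotype link references unknown cell type {link.cell_type!r}")

    @property
    def subjects(self) -> list[tuple[str, str]]:
        """(subject_id, group) pairs, group A first."""
        subs = [(f"A{i + 1:02d}", "A") for i in range(self.n_group_a)]
        subs += [(f"B{i + 1:02d}", "B") for i in range(self.n_group_b)]
        return subs


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must rediscover."""

    spec: SimulationSpec
    design: pd.DataFrame
    # cell type -> probes x subjects matrix of true (noise-free at array level,
    # subject-level deviations included) mean log2 methylation
    true_means: dict[str, pd.DataFrame]
    subject_groups: pd.Series  # subject_id -> 'A' | 'B'

    def dmr_table(self) -> pd.DataFrame:
        """Planted regions as a BED-style table with direction labels."""
        by_id = {l.locus_id: l for l in self.spec.loci}
        rows = [
            {
                "chrom": by_id[d.locus_id].chrom,
                "start": d.start,
                "end": d.end,
                "name": d.label,
                "score": d.effect,
                "locus_id": d.locus_id,
                "direction": "higher_in_A" if d.effect > 0 else "higher_in_B",
            }
            for d in self.spec.planted_dmrs
        ]
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "locus_id", "direction"])


def simulate_design(
    loci, spacing: int, probe_length: int | None = None
) -> pd.DataFrame:
    """Tile each locus with probes at fixed spacing.

    ``loci`` is an iterable of LocusSpec or (locus_id, chrom, start, length)
    tuples.  Probe k of a locus starts at ``start + k * spacing``; every
    probe start strictly inside ``[start, start + length)`` yields a probe.
    ``probe_length`` defaults to the spacing, so probes tile the locus
    contiguously; shorter probes leave gaps between tiles.
    """
    if probe_length is None:
        probe_length = spacing
    if spacing <= 0 or probe_length <= 0:
        raise InvalidSpecError("spacing and probe length must be positive")
    loci = [l if isinstance(l, LocusSpec) else LocusSpec(*l) for l in loci]
    rows = []
    for locus in loci:
        if locus.length <= 0:
            raise InvalidSpecError(f"locus {locus.locus_id!r}: non-positive length")
        n = int(np.ceil(locus.length / spacing))
        for k in range(n):
            pstart = locus.start + k * spacing
            pend = min(pstart + probe_length, locus.start + locus.length)
            rows.append((f"{locus.locus_id}_p{k:05d}", locus.chrom, pstart, pend, locus.locus_id))
    design = pd.DataFrame(rows, columns=["probe_id", "chrom", "start", "end", "locus_id"])
    return validate_probe_design(design)


def _baseline_profile(design: pd.DataFrame, loci: tuple[LocusSpec, ...]) -> np.ndarray:
    """Smooth low-frequency sinusoid per locus (deterministic, no RNG)."""
    base = np.zeros(len(design))
    starts = design["start"].to_numpy()
    for k, locus in enumerate(loci):
        mask = (design["locus_id"] == locus.locus_id).to_numpy()
        phase = 2.0 * np.pi * ((0.37 * (k + 1)) % 1.0)
        base[mask] = 0.5 * np.sin(2.0 * np.pi * (starts[mask] - locus.start) / 25_000.0 + phase)
    return base


def _dmr_effect_vector(spec: SimulationSpec, design: pd.DataFrame, cell_type: str) -> np.ndarray:
    effect = np.zeros(len(design))
    starts = design["start"].to_numpy()
    locus_ids = design["locus_id"].to_numpy()
    for dmr in spec.planted_dmrs:
        if dmr.cell_types is not None and cell_type not in dmr.cell_types:
            continue
        mask = (locus_ids == dmr.locus_id) & (starts >= dmr.start) & (starts < dmr.end)
        effect[mask] += dmr.effect
    return effect


def simulate_cohort(
    spec: SimulationSpec, design: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate two-channel intensities for every array of the study.

    Returns (intensities, sample_sheet, ground_truth).  Intensities are a
    long-format table (array_id, probe_id, bound, input); the sample sheet
    maps arrays to subjects, groups, cell types and replicates.  The same
    spec and seed always produce bit-identical output.
    """
    if design is None:
        design = simulate_design(spec.loci, spec.probe_spacing, spec.probe_length)
    else:
        design = validate_probe_design(design)
        tiled = set(design["locus_id"])
        for dmr in spec.planted_dmrs:
            if dmr.locus_id not in tiled:
                raise InvalidSpecError(f"planted DMR {dmr.label!r}: locus not covered by design")
    n_probes = len(design)
    probe_ids = design["probe_id"].to_numpy()
    baseline = _baseline_profile(design, spec.loci)
    subjects = spec.subjects

    sheet_rows = []
    chunks = []
    true_means: dict[str, pd.DataFrame] = {}
    for c_idx, cell in enumerate(spec.cell_types):
        effect = _dmr_effect_vector(spec, design, cell)
        cell_true = np.empty((n_probes, len(subjects)))
        for s_idx, (subject_id, group) in enumerate(subjects):
            rng_sub = np.random.default_rng(
                np.random.SeedSequence([int(spec.seed) & 0x7FFFFFFF, 11, c_idx, s_idx])
            )
            u = rng_sub.normal(0.0, spec.subject_sd, n_probes)
            mean = baseline + (effect if group == "A" else 0.0) + u
            cell_true[:, s_idx] = mean
            for rep in range(1, spec.n_replicates + 1):
                rng_arr = np.random.default_rng(
                    np.random.SeedSequence([int(spec.seed) & 0x7FFFFFFF, 23, c_idx, s_idx, rep])
                )
                array_offset = rng_arr.normal(0.0, spec.replicate_sd)
                log_ratio = mean + array_offset + rng_arr.normal(0.0, spec.probe_noise_sd, n_probes)
                input_channel = np.exp2(rng_arr.normal(10.0, 0.5, n_probes))
                bound = input_channel * np.exp2(log_ratio)
                array_id = f"{subject_id}_{cell}_r{rep}"
                sheet_rows.append((array_id, subject_id, group, cell, rep))
                chunks.append(
                    pd.DataFrame(
                        {
                            "array_id": array_id,
                            "probe_id": probe_ids,
                            "bound": bound,
                            "input": input_channel,
                        }
                    )
                )
        true_means[cell] = pd.DataFrame(
            cell_true, index=pd.Index(probe_ids, name="probe_id"), columns=[s for s, _ in subjects]
        )

    intensities = pd.concat(chunks, ignore_index=True)
    sheet = pd.DataFrame(
        sheet_rows, columns=["array_id", "subject_id", "group", "cell_type", "replicate"]
    )
    groups = pd.Series({s: g for s, g in subjects}, name="group")
    truth = GroundTruth(spec=spec, design=design, true_means=true_means, subject_groups=groups)
    return intensities, sheet, truth


def simulate_phenotype(
    truth: GroundTruth, links=None, seed: int | None = None
) -> pd.DataFrame:
    """Per-subject phenotype levels linearly linked to planted-region methylation.

    ``links`` defaults to the links of the generating spec; ``seed`` defaults
    to the spec seed.  Returns a long table (subject_id, analyte, level).
    """
    spec = truth.spec
    if links is None:
        links = spec.phenotype_links
    if seed is None:
        seed = spec.seed
    dmrs = {d.label: d for d in spec.planted_dmrs}
    design = truth.design
    rows = []
    for l_idx, link in enumerate(links):
        if link.region not in dmrs:
            raise InvalidSpecError(f"phenotype link references unknown region {link.region!r}")
        dmr = dmrs[link.region]
        cell = link.cell_type or spec.cell_types[0]
        if cell not in truth.true_means:
            raise InvalidSpecError(f"phenotype link references unknown cell type {cell!r}")
        mask = (
            (design["locus_id"] == dmr.locus_id)
            & (design["start"] >= dmr.start)
            & (design["start"] < dmr.end)
        ).to_numpy()
        region_mean = truth.true_means[cell].loc[mask].mean(axis=0)
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 31, l_idx]))
        noise = rng.normal(0.0, link.noise_sd, len(region_mean))
        levels = link.intercept + link.slope * region_mean.to_numpy() + noise
        for subject_id, level in zip(region_mean.index, levels):
            rows.append((subject_id, link.analyte, level))
    return pd.DataFrame(rows, columns=["subject_id", "analyte", "level"])


def simulate_tracks(
    design: pd.DataFrame,
    density: float,
    mean_width: float,
    names,
    seed: int,
    track_names=("TFBS", "DNase"),
) -> list[AnnotationTrack]:
    """Random BED-style regulatory tracks over the tiled spans.

    ``density`` is the expected number of elements per 10 kb of tiled span
    (Poisson counts); element widths are exponential around ``mean_width``
    and element names are drawn uniformly from ``names``.
    """
    names = list(names)
    if not names:
        raise InvalidSpecError("element name list must be non-empty")
    if density <= 0:
        raise InvalidSpecError("density must be positive")
    spans = design.groupby("locus_id", sort=True).agg(
        chrom=("chrom", "first"), lo=("start", "min"), hi=("end", "max")
    )
    tracks = []
    for t_idx, track_name in enumerate(track_names):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 41, t_idx]))
        rows = []
        for _, span in spans.iterrows():
            span_len = int(span.hi - span.lo)
            n = rng.poisson(density * span_len / 10_000.0)
            for _ in range(n):
                start = int(rng.integers(span.lo, span.hi))
                width = max(1, int(round(rng.exponential(mean_width))))
                rows.append((span.chrom, start, start + width, names[rng.integers(len(names))], 0.0))
        tracks.append(
            AnnotationTrack(
                name=track_name,
                intervals=pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"]),
            )
        )
    return tracks


# ---------------------------------------------------------------------------
# ready-made study layouts


def study_loci() -> tuple[LocusSpec, ...]:
    """Eight loci mirroring a five-cytokine / three-transcription-factor panel.

    Lengths are in the ~100-180 kb range typical of a locus-wide tiling
    design that extends ~40 kb beyond each gene.
    """
    return (
        LocusSpec("IL1A", "chr2", 113_200_000, 140_000),
        LocusSpec("IL6", "chr7", 22_700_000, 120_000),
        LocusSpec("IL8", "chr4", 74_570_000, 100_000),
        LocusSpec("IL4", "chr5", 132_000_000, 180_000),
        LocusSpec("IL10", "chr1", 206_900_000, 120_000),
        LocusSpec("NFKB1", "chr4", 103_380_000, 160_000),
        LocusSpec("NFAT5", "chr16", 69_560_000, 180_000),
        LocusSpec("STAT6", "chr12", 57_460_000, 120_000),
    )


def study_gene_models(loci=None) -> pd.DataFrame:
    """Plus-strand gene models with the TSS 40 kb into each tiled locus."""
    loci = tuple(loci) if loci is not None else study_loci()
    rows = []
    for locus in loci:
        tss = locus.start + min(40_000, locus.length // 3)
        tes = locus.start + locus.length - min(40_000, locus.length // 3)
        rows.append((locus.locus_id, locus.chrom, tss, "+", max(tes, tss + 1000)))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand", "tes"])


def study_spec(seed: int = 0, loci=None, **overrides) -> SimulationSpec:
    """A SimulationSpec with the emulated study's sample sizes and noise defaults."""
    loci = tuple(loci) if loci is not None else study_loci()
    return SimulationSpec(loci=loci, seed=seed, **overrides)
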
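"""Annotation of called regions against gene models and regulatory tracks.

Each region is assigned its nearest gene by absolute distance from the
region midpoint to the transcription start site (TSS).  Distances are
signed and strand-oriented: negative means upstream of the TSS on the
gene's strand.  A region is flagged as promoter-proximal when its midpoint
lies within the window from 2000 bp upstream to 1000 bp downstream of the
TSS.  Regulatory-element overlap is binary: an element overlaps a region if
the half-open intersection is at least 1 bp.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import AnnotationTrack, validate_gene_models

PROMOTER_UPSTREAM = 2000
PROMOTER_DOWNSTREAM = 1000


def tss_distance(midpoint: float, tss: int, strand: str) -> float:
    """Signed strand-oriented distance from a point to a TSS (upstream < 0)."""
    d = midpoint - tss
    return d if strand == "+" else -d


def assign_nearest_gene(
    region, genes: pd.DataFrame,
    promoter_upstream: int = PROMOTER_UPSTREAM,
    promoter_downstream: int = PROMOTER_DOWNSTREAM,
) -> tuple[str | None, float | None, bool]:
    """Nearest gene (by |midpoint - TSS|), signed TSS distance and promoter flag.

    ``region`` is any mapping/namedtuple with chrom, start, end.  Ties are
    broken by lexicographically smaller gene_id.  With no gene on the
    region's chromosome the record is left unannotated (None, None, False).
    """
    genes = validate_gene_models(genes)
    chrom = region["chrom"] if isinstance(region, (dict, pd.Series)) else region.chrom
    start = region["start"] if isinstance(region, (dict, pd.Series)) else region.start
    end = region["end"] if isinstance(region, (dict, pd.Series)) else region.end
    candidates = genes[genes["chrom"] == chrom]
    if len(candidates) == 0:
        return None, None, False
    midpoint = (start + end) / 2.0
    dist = (midpoint - candidates["tss"]).abs()
    best = candidates.assign(_d=dist).sort_values(["_d", "gene_id"], kind="mergesort").iloc[0]
    signed = tss_distance(midpoint, int(best["tss"]), str(best["strand"]))
    promoter = -promoter_upstream <= signed <= promoter_downstream
    return str(best["gene_id"]), float(signed), bool(promoter)


def _track_trees(track: AnnotationTrack) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for row in track.intervals.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, row.name)
    return trees


def overlap_tracks(regions: pd.DataFrame, tracks: list[AnnotationTrack]) -> pd.DataFrame:
    """Element names of each track overlapping each region (>= 1 bp, half-open).

    Returns one row per region with a column per track holding the
    deduplicated, first-occurrence-ordered element names (list).
    """
    out = {track.name: [] for track in tracks}
    trees = {track.name: _track_trees(track) for track in tracks}
    for region in regions.itertuples(index=False):
        for track in tracks:
            tree = trees[track.name].get(region.chrom)
            hits = sorted(tree.overlap(region.start, region.end), key=lambda iv: (iv.begin, iv.end, str(iv.data))) if tree else []
            seen: list[str] = []
            for iv in hits:
                if iv.data not in seen:
                    seen.append(iv.data)
            out[track.name].append(seen)
    frame = pd.DataFrame(out)
    frame.insert(0, "region_id", regions["region_id"].to_numpy() if "region_id" in regions else np.arange(len(regions)))
    return frame


def annotate_regions(
    regions: pd.DataFrame,
    genes: pd.DataFrame,
    tracks: list[AnnotationTrack] | None = None,
    promoter_upstream: int = PROMOTER_UPSTREAM,
    promoter_downstream: int = PROMOTER_DOWNSTREAM,
) -> pd.DataFrame:
    """Full annotation records for a table of (called) regions."""
    tracks = tracks or []
    rows = []
    for region in regions.itertuples(index=False):
        gene, dist, promoter = assign_nearest_gene(
            region, genes, promoter_upstream, promoter_downstream
        )
        rows.append(
            {
                "region_id": region.region_id,
                "nearest_gene": gene,
                "tss_distance": dist,
                "promoter": promoter,
            }
        )
    records = pd.DataFrame(
        rows, columns=["region_id", "nearest_gene", "tss_distance", "promoter"]
    )
    if tracks:
        overlaps = overlap_tracks(regions, tracks)
        for track in tracks:
            records[track.name] = [",".join(v) for v in overlaps[track.name]]
            records[f"{track.name}_overlap"] = [len(v) > 0 for v in overlaps[track.name]]
    return records


def summarize_overlaps(records: pd.DataFrame, tracks: list[AnnotationTrack]) -> dict[str, int]:
    """Number of distinct regions with at least one overlapping element, per track."""
    return {
        track.name: int(records[f"{track.name}_overlap"].sum()) if f"{track.name}_overlap" in records else 0
        for track in tracks
    }
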
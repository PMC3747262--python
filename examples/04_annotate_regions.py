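"""Annotate called regions with nearest gene, TSS distance and regulatory tracks.

Regions are placed relative to a plus-strand gene model; overlap with
simulated transcription-factor-binding-site and DNase tracks is binary
(>= 1 bp).  The promoter window is TSS-2000 to TSS+1000, strand-oriented.
"""

import pandas as pd

import tilemeth as tm

genes = pd.DataFrame(
    {"gene_id": ["IL6"], "chrom": ["chr7"], "tss": [22_740_000], "strand": ["+"], "tes": [22_746_000]}
)
regions = pd.DataFrame(
    [
        {"region_id": "r_promoter", "chrom": "chr7", "start": 22_738_700, "end": 22_739_700},
        {"region_id": "r_just_outside", "chrom": "chr7", "start": 22_737_458, "end": 22_738_458},
        {"region_id": "r_distal", "chrom": "chr7", "start": 22_715_000, "end": 22_716_000},
    ]
)
design = tm.simulate_design([("IL6", "chr7", 22_700_000, 50_000)], 100)
tracks = tm.simulate_tracks(design, density=8.0, mean_width=600,
                            names=["NFkB", "PU.1", "c-Jun"], seed=7)

records = tm.annotate_regions(regions, genes, tracks)
print(records.to_string(index=False))
print("\nregions overlapping each track:", tm.summarize_overlaps(records, tracks))
# tss_distance is signed and strand-oriented (negative = upstream); the
# midpoint of r_just_outside sits at -2042 bp, outside the promoter window.
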
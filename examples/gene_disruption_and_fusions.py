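"""Annotate a balanced call with disrupted genes and fusion candidates.

A hand-built 5-SV balanced cluster hits two genes; one junction joins the 5'
part of gene A to the 3' part of gene B in a compatible orientation,
producing an A->B fusion candidate.
"""

from chromobal import (
    Breakend,
    CNProfile,
    CNSegment,
    GeneRecord,
    call_cluster,
    disrupted_genes,
    fusion_candidates,
    make_sv,
)
from chromobal.clustering import detect_clusters

MB = 1_000_000

svs = [
    make_sv("j1", Breakend("chrY", 10 * MB, "+"), Breakend("chrY", 20 * MB, "-")),
    make_sv("j2", Breakend("chrY", 11 * MB, "+"), Breakend("chrY", 18 * MB, "-")),
    make_sv("j3", Breakend("chrY", 12 * MB, "-"), Breakend("chrY", 19 * MB, "+")),
    make_sv("j4", Breakend("chrY", 13 * MB, "+"), Breakend("chrY", 17 * MB, "+")),
    make_sv("j5", Breakend("chrY", 14 * MB, "-"), Breakend("chrY", 16 * MB, "-")),
]
genes = [
    GeneRecord("chrY", 10 * MB - 30_000, 10 * MB + 40_000, "+", "GENE_A", is_driver=True),
    GeneRecord("chrY", 20 * MB - 50_000, 20 * MB + 20_000, "+", "GENE_B"),
]
profile = CNProfile.from_segments([CNSegment("chrY", 0, 57_227_415, 1)])

(cluster,) = detect_clusters(svs, min_sv=5)
call = call_cluster(cluster, svs, profile, chromoplexy_regions=[])
print(f"classification: {call.classification}")

(impact,) = disrupted_genes([call], genes, pad=5_000)
print(f"disrupted genes: {[g.name for g in impact.disrupted]}")
print(f"driver hits: {[g.name for g in impact.driver_hits]}")

for cand in fusion_candidates([call], genes):
    print(f"fusion candidate: {cand.gene5.name} (5') -> {cand.gene3.name} (3') "
          f"via junction {cand.junction_id}")
# j1 cuts GENE_A retaining its 5' part (+ strand, side +) and GENE_B
# retaining its 3' part (side -): an orientation-compatible fusion.
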
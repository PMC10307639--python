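"""Gene disruption and fusion-candidate annotation for balanced calls.

A gene is *disrupted* by a call when any breakend of a member SV falls within
the gene body padded by ``pad`` bp on each side (default 5 kb). Driver hits
are the disrupted genes flagged in the driver catalogue.

Fusion candidates use the standard 5'/3' retained-part compatibility test:
a junction whose two breakends fall in two different genes can fuse them only
if one partner retains its 5' part and the other its 3' part. With the side
convention ("+" keeps sequence left of pos, "-" keeps sequence right), the
retained part of a gene on strand ``g`` cut by a breakend with side ``s`` is
the 5' part when ``g == s`` and the 3' part otherwise. This orientation rule
is a heuristic: no reading-frame or expression check is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .caller import ChromothripsisCall
from .genome import Breakend, GeneRecord


@dataclass(frozen=True)
class FusionCandidate:
    gene5: GeneRecord
    gene3: GeneRecord
    junction_id: str
    breakend5: Breakend
    breakend3: Breakend


@dataclass
class GeneImpact:
    """Disrupted genes, driver hits and fusion candidates of one call."""

    call: ChromothripsisCall
    disrupted: dict[GeneRecord, list[Breakend]] = field(default_factory=dict)
    fusions: list[FusionCandidate] = field(default_factory=list)

    @property
    def driver_hits(self) -> list[GeneRecord]:
        return [g for g in self.disrupted if g.is_driver]


def _gene_trees(genes: list[GeneRecord], pad: int) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start - pad, g.end + pad, g)
    return trees


def disrupted_genes(
    calls: list[ChromothripsisCall], genes: list[GeneRecord], pad: int = 5_000
) -> list[GeneImpact]:
    """Map member-SV breakends onto padded gene bodies.

    Every overlapping gene is reported (no precedence between overlapping
    genes); each (gene, call) pair appears once with all contributing
    breakends. Output order follows the input call and gene order.
    """
    if pad < 0:
        raise ValueError("pad must be >= 0")
    trees = _gene_trees(genes, pad)
    order = {g: i for i, g in enumerate(genes)}
    impacts = []
    for call in calls:
        hit: dict[GeneRecord, list[Breakend]] = {}
        for sv in call.cluster.members:
            for bnd in sv.breakends():
                tree = trees.get(bnd.chrom)
                if tree is None:
                    continue
                for iv in tree.at(bnd.pos):
                    hit.setdefault(iv.data, []).append(bnd)
        ordered = {g: hit[g] for g in sorted(hit, key=order.__getitem__)}
        impacts.append(GeneImpact(call=call, disrupted=ordered))
    return impacts


def _retained_part(gene: GeneRecord, bnd: Breakend) -> str:
    """'5p' or '3p': which part of the gene the junction keeps attached."""
    return "5p" if gene.strand == bnd.side else "3p"


def fusion_candidates(
    calls: list[ChromothripsisCall], genes: list[GeneRecord]
) -> list[FusionCandidate]:
    """Orientation-compatible gene-fusion candidates among member junctions.

    A candidate needs the two breakends of one junction inside two *different*
    gene bodies (unpadded), one partner retaining its 5' part and the other
    its 3' part; the 5'-retaining gene is the 5' fusion partner.
    """
    trees = _gene_trees(genes, pad=0)
    out: list[FusionCandidate] = []
    for call in calls:
        for sv in call.cluster.members:
            b1, b2 = sv.breakends()
            genes1 = [iv.data for iv in trees.get(b1.chrom, IntervalTree()).at(b1.pos)]
            genes2 = [iv.data for iv in trees.get(b2.chrom, IntervalTree()).at(b2.pos)]
            for g1 in genes1:
                for g2 in genes2:
                    if g1 == g2:
                        continue  # intragenic junction
                    p1, p2 = _retained_part(g1, b1), _retained_part(g2, b2)
                    if p1 == "5p" and p2 == "3p":
                        out.append(FusionCandidate(g1, g2, sv.id, b1, b2))
                    elif p1 == "3p" and p2 == "5p":
                        out.append(FusionCandidate(g2, g1, sv.id, b2, b1))
    return out


def impacts_to_table(impacts: list[GeneImpact], sample_id: str = "") -> pd.DataFrame:
    rows = []
    for imp in impacts:
        for gene, bnds in imp.disrupted.items():
            rows.append(
                {
                    "sample": sample_id,
                    "chrom": imp.call.cluster.chrom,
                    "gene": gene.name,
                    "is_driver": gene.is_driver,
                    "breakpoints": ",".join(f"{b.chrom}:{b.pos}" for b in bnds),
                }
            )
    return pd.DataFrame(
        rows, columns=["sample", "chrom", "gene", "is_driver", "breakpoints"]
    )


def fusions_to_table(fusions: list[FusionCandidate], sample_id: str = "") -> pd.DataFrame:
    rows = [
        {
            "sample": sample_id,
            "gene5": f.gene5.name,
            "gene3": f.gene3.name,
            "junction": f.junction_id,
            "breakend5": f"{f.breakend5.chrom}:{f.breakend5.pos}:{f.breakend5.side}",
            "breakend3": f"{f.breakend3.chrom}:{f.breakend3.pos}:{f.breakend3.side}",
        }
        for f in fusions
    ]
    return pd.DataFrame(
        rows, columns=["sample", "gene5", "gene3", "junction", "breakend5", "breakend3"]
    )


__all__ = [
    "GeneImpact",
    "FusionCandidate",
    "disrupted_genes",
    "fusion_candidates",
    "impacts_to_table",
    "fusions_to_table",
]
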
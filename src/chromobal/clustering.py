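"""Per-chromosome clustering of intrachromosomal SVs.

A chromothripsis candidate is a connected group of SV footprints: each
intrachromosomal junction occupies the interval between its two breakends,
and two junctions are linked when their footprints overlap or lie within
``gap_max`` of one another. Connected components with at least ``min_sv``
members form clusters. Translocations never join clusters; they are consulted
later by the balanced filter.

The interleaving fraction is a diagnostic of the "random rejoining" geometry:
among footprint pairs that overlap, the fraction where neither footprint
contains the other. Nested pairs (one inside the other) suggest hierarchical
events rather than a single shattering.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .genome import SVRecord


@dataclass
class SVCluster:
    """A cluster of intrachromosomal SVs on one chromosome."""

    chrom: str
    members: list[SVRecord]
    span_start: int = field(init=False)
    span_end: int = field(init=False)
    n_intra: int = field(init=False)
    interleave_frac: float | None = field(init=False, default=None)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster needs at least one member")
        if any(sv.chrom != self.chrom for sv in self.members):
            raise ValueError("cluster members must share one chromosome")
        positions = [p for sv in self.members for p in sv.footprint]
        self.span_start = min(positions)
        self.span_end = max(positions)
        self.n_intra = len(self.members)
        if self.n_intra >= 2:
            self.interleave_frac = interleaving_fraction(self)

    @property
    def class_counts(self) -> Counter:
        return Counter(sv.sv_class for sv in self.members)


def detect_clusters(
    svs: list[SVRecord], min_sv: int = 5, gap_max: int = 1_000_000
) -> list[SVCluster]:
    """Group intrachromosomal SVs into footprint-linked clusters.

    Parameters
    ----------
    svs:
        SV records; TRA records are ignored for membership.
    min_sv:
        Minimum members per reported cluster (>= 1).
    gap_max:
        Two footprints link when within this many bp of each other
        (0 = require overlap/touch).

    Returns clusters sorted by (chrom, span_start). For interval graphs the
    connected components equal the groups produced by a sorted sweep, which
    is what is implemented; an O(n^2) union-find oracle checks this in tests.
    """
    if min_sv < 1:
        raise ValueError("min_sv must be >= 1")
    by_chrom: dict[str, list[SVRecord]] = {}
    for sv in svs:
        if sv.is_intra:
            by_chrom.setdefault(sv.chrom, []).append(sv)

    clusters: list[SVCluster] = []
    for chrom in sorted(by_chrom):
        recs = sorted(by_chrom[chrom], key=lambda sv: sv.footprint)
        group: list[SVRecord] = []
        reach = None  # rightmost footprint end of the open group, plus gap
        for sv in recs:
            start, end = sv.footprint
            if reach is None or start <= reach:
                group.append(sv)
            else:
                if len(group) >= min_sv:
                    clusters.append(SVCluster(chrom, group))
                group = [sv]
                reach = None
            reach = end + gap_max if reach is None else max(reach, end + gap_max)
        if len(group) >= min_sv:
            clusters.append(SVCluster(chrom, group))
    clusters.sort(key=lambda c: (c.chrom, c.span_start))
    return clusters


def interleaving_fraction(cluster: SVCluster) -> float:
    """Fraction of overlapping member-footprint pairs that interleave.

    A pair interleaves when the footprints overlap and neither contains the
    other. Returns 0.0 when no pair overlaps. Requires >= 2 members.
    """
    members = cluster.members
    if len(members) < 2:
        raise ValueError("interleaving fraction needs >= 2 members")
    overlapping = 0
    interleaved = 0
    fps = [sv.footprint for sv in members]
    for i in range(len(fps)):
        s1, e1 = fps[i]
        for j in range(i + 1, len(fps)):
            s2, e2 = fps[j]
            if max(s1, s2) > min(e1, e2):
                continue  # disjoint
            overlapping += 1
            nested = (s1 <= s2 and e2 <= e1) or (s2 <= s1 and e1 <= e2)
            if not nested:
                interleaved += 1
    return interleaved / overlapping if overlapping else 0.0


def clusters_to_table(clusters: list[SVCluster], sample_id: str = "") -> pd.DataFrame:
    """Cluster summary table (one row per cluster)."""
    rows = []
    for c in clusters:
        counts = c.class_counts
        rows.append(
            {
                "sample": sample_id,
                "chrom": c.chrom,
                "span_start": c.span_start,
                "span_end": c.span_end,
                "n_intra": c.n_intra,
                "interleave_frac": c.interleave_frac,
                "DEL": counts.get("DEL", 0),
                "DUP": counts.get("DUP", 0),
                "h2hINV": counts.get("h2hINV", 0),
                "t2tINV": counts.get("t2tINV", 0),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample", "chrom", "span_start", "span_end", "n_intra",
            "interleave_frac", "DEL", "DUP", "h2hINV", "t2tINV",
        ],
    )


__all__ = [
    "SVCluster",
    "detect_clusters",
    "interleaving_fraction",
    "clusters_to_table",
]
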
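"""The balanced-chromothripsis caller.

A cluster of intrachromosomal SVs is classified *balanced* when it satisfies
four criteria:

1. at least ``min_sv`` intrachromosomal SVs (default 5);
2. no translocation breakend maps within the genomic span of the cluster
   (distinguishes balanced chromothripsis from chromoplexy chains, which also
   show limited DNA loss);
3. no overlap with known chromoplexy regions, when such calls are supplied;
4. less than ``max_loss_frac`` (default 1%) of the cluster span shows a total
   copy number below the chromosome's modal copy number (excludes canonical,
   loss-bearing chromothripsis).

All criteria are evaluated (no short-circuit) so every failure mode is
reported; the reject-reason ledger is the machine-readable replacement for a
manual review of rearrangement plots. A cluster failing only the loss
criterion while showing a long two-state CN oscillation is labelled
``canonical_like`` as a contrast class; this is a heuristic label, not a
canonical-chromothripsis caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .clustering import SVCluster
from .cn_metrics import (
    CNProfile,
    UncallableSpanError,
    modal_copy_number,
    oscillation_run_length,
    span_cn_stats,
)
from .genome import SVRecord

CLASSIFICATIONS = ("balanced", "canonical_like", "rejected")

REJECT_REASONS = (
    "too_few_sv",
    "translocation_in_span",
    "chromoplexy_overlap",
    "loss_fraction_exceeded",
    "uncallable_span",
    "low_interleave",
)


@dataclass(frozen=True)
class CallThresholds:
    """Numeric criteria of the balanced caller.

    ``min_interleave`` gates on the interleaving diagnostic only when > 0
    (off by default, so counts follow the four explicit criteria alone).
    ``canonical_min_oscillations`` is the merged-segment run length above
    which a loss-failing cluster is labelled canonical_like.
    """

    min_sv: int = 5
    max_loss_frac: float = 0.01
    gene_pad: int = 5_000
    gap_max: int = 1_000_000
    min_interleave: float = 0.0
    canonical_min_oscillations: int = 7

    def __post_init__(self) -> None:
        if self.min_sv < 1:
            raise ValueError("min_sv must be >= 1")
        if not 0.0 <= self.max_loss_frac <= 1.0:
            raise ValueError("max_loss_frac must be in [0, 1]")
        if self.gene_pad < 0 or self.gap_max < 0:
            raise ValueError("gene_pad and gap_max must be >= 0")


@dataclass
class ChromothripsisCall:
    """A cluster plus its classification and all filter metrics."""

    cluster: SVCluster
    classification: str
    reject_reasons: list[str]
    metrics: dict = field(default_factory=dict)

    @property
    def is_balanced(self) -> bool:
        return self.classification == "balanced"


def translocations_in_span(
    all_svs: list[SVRecord], chrom: str, span_start: int, span_end: int
) -> int:
    """Count TRA records with >=1 breakend inside [span_start, span_end) on chrom."""
    count = 0
    for sv in all_svs:
        if sv.sv_class != "TRA":
            continue
        for bnd in sv.breakends():
            if bnd.chrom == chrom and span_start <= bnd.pos < span_end:
                count += 1
                break
    return count


def _overlaps_regions(
    regions: list[tuple[str, int, int]], chrom: str, start: int, end: int
) -> bool:
    return any(
        rchrom == chrom and max(rstart, start) < min(rend, end)
        for rchrom, rstart, rend in regions
    )


def call_cluster(
    cluster: SVCluster,
    all_svs: list[SVRecord],
    profile: CNProfile,
    chromoplexy_regions: list[tuple[str, int, int]] | None = None,
    thr: CallThresholds = CallThresholds(),
) -> ChromothripsisCall:
    """Evaluate the four balanced-chromothripsis criteria for one cluster.

    ``chromoplexy_regions=None`` means no chromoplexy calls were supplied:
    criterion 3 is recorded as not evaluated (``chromoplexy_evaluated`` in
    the metrics) rather than silently passed.
    """
    reasons: list[str] = []
    span_start, span_end = cluster.span_start, cluster.span_end
    metrics: dict = {
        "n_intra": cluster.n_intra,
        "interleave_frac": cluster.interleave_frac,
        "chromoplexy_evaluated": chromoplexy_regions is not None,
    }

    if cluster.n_intra < thr.min_sv:
        reasons.append("too_few_sv")

    n_tra = translocations_in_span(all_svs, cluster.chrom, span_start, span_end)
    metrics["n_tra_in_span"] = n_tra
    if n_tra > 0:
        reasons.append("translocation_in_span")

    if chromoplexy_regions is not None and _overlaps_regions(
        chromoplexy_regions, cluster.chrom, span_start, span_end
    ):
        reasons.append("chromoplexy_overlap")

    modal = modal_copy_number(profile)
    metrics["modal_cn"] = modal
    try:
        stats = span_cn_stats(profile, span_start, span_end, modal)
        metrics.update(
            loss_frac=stats.loss_frac,
            gain_frac=stats.gain_frac,
            uncovered_frac=stats.uncovered_frac,
        )
        metrics["oscillation_run"] = oscillation_run_length(profile, span_start, span_end)
        if stats.loss_frac >= thr.max_loss_frac:
            reasons.append("loss_fraction_exceeded")
    except UncallableSpanError:
        metrics.update(
            loss_frac=None, gain_frac=None, uncovered_frac=1.0, oscillation_run=None
        )
        reasons.append("uncallable_span")

    if thr.min_interleave > 0 and (cluster.interleave_frac or 0.0) < thr.min_interleave:
        reasons.append("low_interleave")

    if not reasons:
        classification = "balanced"
    elif (
        reasons == ["loss_fraction_exceeded"]
        and (metrics.get("oscillation_run") or 0) >= thr.canonical_min_oscillations
    ):
        classification = "canonical_like"
    else:
        classification = "rejected"
    return ChromothripsisCall(cluster, classification, reasons, metrics)


@dataclass
class SampleSummary:
    """Per-sample tally of classifications."""

    sample_id: str
    n_clusters: int
    n_balanced: int
    n_canonical_like: int
    n_rejected: int
    balanced_chromosomes: tuple[str, ...]
    multi_chromosome: bool


def summarize_sample(calls: list[ChromothripsisCall], sample_id: str) -> SampleSummary:
    """Count classifications and flag balanced events on >1 chromosome."""
    balanced_chroms = sorted({c.cluster.chrom for c in calls if c.is_balanced})
    tally = {k: sum(c.classification == k for c in calls) for k in CLASSIFICATIONS}
    return SampleSummary(
        sample_id=sample_id,
        n_clusters=len(calls),
        n_balanced=tally["balanced"],
        n_canonical_like=tally["canonical_like"],
        n_rejected=tally["rejected"],
        balanced_chromosomes=tuple(balanced_chroms),
        multi_chromosome=len(balanced_chroms) > 1,
    )


def calls_to_table(calls: list[ChromothripsisCall], sample_id: str = "") -> pd.DataFrame:
    """One row per call with classification, reasons and all metrics."""
    rows = []
    for call in calls:
        m = call.metrics
        rows.append(
            {
                "sample": sample_id,
                "chrom": call.cluster.chrom,
                "span_start": call.cluster.span_start,
                "span_end": call.cluster.span_end,
                "classification": call.classification,
                "reject_reasons": ";".join(call.reject_reasons),
                "n_intra": m.get("n_intra"),
                "n_tra_in_span": m.get("n_tra_in_span"),
                "loss_frac": m.get("loss_frac"),
                "gain_frac": m.get("gain_frac"),
                "uncovered_frac": m.get("uncovered_frac"),
                "modal_cn": m.get("modal_cn"),
                "oscillation_run": m.get("oscillation_run"),
                "interleave_frac": m.get("interleave_frac"),
                "chromoplexy_evaluated": m.get("chromoplexy_evaluated"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample", "chrom", "span_start", "span_end", "classification",
            "reject_reasons", "n_intra", "n_tra_in_span", "loss_frac",
            "gain_frac", "uncovered_frac", "modal_cn", "oscillation_run",
            "interleave_frac", "chromoplexy_evaluated",
        ],
    )


__all__ = [
    "CLASSIFICATIONS",
    "REJECT_REASONS",
    "CallThresholds",
    "ChromothripsisCall",
    "SampleSummary",
    "translocations_in_span",
    "call_cluster",
    "summarize_sample",
    "calls_to_table",
]
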
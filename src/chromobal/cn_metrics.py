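"""Copy-number statistics for the balanced filter.

Three quantities drive the classification of a cluster:

* the chromosome's *modal* total copy number — the CN value covering the
  greatest summed segment length, the reference level against which loss is
  measured;
* the *loss fraction* of a span — the fraction of CN-covered bases within the
  cluster span whose total CN lies below the modal value (balanced calls
  require < 1%);
* the longest *two-state oscillation run* — the classic canonical
  chromothripsis signature of CN alternating between exactly two values.

All statistics use total copy number. Bases not covered by any CN segment are
excluded from loss/gain denominators and their fraction is reported, since
silently counting them either way would bias the statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .genome import CNSegment, validate_cn_segments

logger = logging.getLogger(__name__)

UNCOVERED_WARN_FRAC = 0.10


class UncallableSpanError(ValueError):
    """A span with zero copy-number coverage cannot be evaluated."""


@dataclass(frozen=True)
class CNProfile:
    """Sorted, non-overlapping CN segments of one chromosome."""

    chrom: str
    segments: tuple[CNSegment, ...]

    @classmethod
    def from_segments(cls, segments: list[CNSegment], chrom: str | None = None) -> "CNProfile":
        segs = [s for s in segments if chrom is None or s.chrom == chrom]
        if not segs:
            raise ValueError(f"no CN segments for chromosome {chrom!r}")
        chroms = {s.chrom for s in segs}
        if len(chroms) > 1:
            raise ValueError(f"profile mixes chromosomes {sorted(chroms)}")
        return cls(chroms.pop(), tuple(validate_cn_segments(segs)))

    @property
    def covered_length(self) -> int:
        return sum(s.length for s in self.segments)


def modal_copy_number(profile: CNProfile) -> int:
    """Length-weighted mode of total CN; ties break toward the lower value."""
    if not profile.segments:
        raise ValueError("empty CN profile")
    weight: dict[int, int] = {}
    for seg in profile.segments:
        weight[seg.total_cn] = weight.get(seg.total_cn, 0) + seg.length
    # max length, then lowest CN on ties
    return min(cn for cn, w in weight.items() if w == max(weight.values()))


@dataclass(frozen=True)
class SpanCNStats:
    """Loss/gain statistics of a span relative to a modal copy number."""

    loss_frac: float     # covered fraction with total CN < modal
    gain_frac: float     # covered fraction with total CN > modal (diagnostic)
    covered: int         # bp of the span covered by CN segments
    uncovered_frac: float  # fraction of the span without CN coverage


def span_cn_stats(
    profile: CNProfile, span_start: int, span_end: int, modal: int
) -> SpanCNStats:
    """Clip segments to [span_start, span_end) and tally loss/gain lengths.

    Raises :class:`UncallableSpanError` when the span has zero CN coverage.
    """
    if span_start >= span_end:
        raise ValueError("span_start must be < span_end")
    covered = loss = gain = 0
    for seg in profile.segments:
        lo = max(seg.start, span_start)
        hi = min(seg.end, span_end)
        if lo >= hi:
            continue
        covered += hi - lo
        if seg.total_cn < modal:
            loss += hi - lo
        elif seg.total_cn > modal:
            gain += hi - lo
    if covered == 0:
        raise UncallableSpanError(
            f"span {profile.chrom}:{span_start}-{span_end} has no CN coverage"
        )
    span_len = span_end - span_start
    uncovered_frac = (span_len - covered) / span_len
    if uncovered_frac > UNCOVERED_WARN_FRAC:
        logger.warning(
            "span %s:%d-%d: %.1f%% of the span lacks CN coverage",
            profile.chrom, span_start, span_end, 100 * uncovered_frac,
        )
    return SpanCNStats(loss / covered, gain / covered, covered, uncovered_frac)


def loss_fraction_below_modal(
    profile: CNProfile, span_start: int, span_end: int, modal: int
) -> float:
    """Fraction of the covered span with total CN below ``modal``."""
    return span_cn_stats(profile, span_start, span_end, modal).loss_frac


def oscillation_run_length(profile: CNProfile, span_start: int, span_end: int) -> int:
    """Longest run of clipped, merged segments alternating between two CN values.

    Segments are clipped to the span and consecutive equal-CN segments merged;
    the result is the length (in merged segments) of the longest contiguous
    run whose values alternate between exactly two states. A single segment
    counts as a run of 1.
    """
    values: list[int] = []
    for seg in profile.segments:
        if min(seg.end, span_end) <= max(seg.start, span_start):
            continue
        if not values or values[-1] != seg.total_cn:
            values.append(seg.total_cn)
    if not values:
        raise UncallableSpanError(
            f"span {profile.chrom}:{span_start}-{span_end} intersects no CN segments"
        )
    best = 1
    run_start = 0
    for i in range(2, len(values)):
        if values[i] != values[i - 2]:
            run_start = i - 1
        best = max(best, i - run_start + 1)
    if len(values) >= 2:
        best = max(best, 2)
    return best


__all__ = [
    "CNProfile",
    "SpanCNStats",
    "UncallableSpanError",
    "modal_copy_number",
    "loss_fraction_below_modal",
    "span_cn_stats",
    "oscillation_run_length",
]
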
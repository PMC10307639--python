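"""Core data model: genome build, breakends, SV records, CN segments, genes.

Coordinate convention
---------------------
All internal coordinates are 0-based; intervals are half-open ``[start, end)``.
A breakend's ``side`` says which flank of ``pos`` the junction retains:

* ``"+"`` — the junction joins the sequence to the LEFT of ``pos`` (a fragment
  that ends at ``pos``);
* ``"-"`` — the junction joins the sequence to the RIGHT of ``pos`` (a fragment
  that starts at ``pos``).

With breakends ordered by position, the side pair determines the orientation
class of an intrachromosomal junction::

    (+, -) -> DEL      deletion-like
    (-, +) -> DUP      duplication-like
    (+, +) -> h2hINV   head-to-head inversion
    (-, -) -> t2tINV   tail-to-tail inversion

Interchromosomal junctions are class ``TRA``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

SV_CLASSES = ("DEL", "DUP", "h2hINV", "t2tINV", "TRA")

# classification table keyed by the (low, high) side pair after ordering
_SIDE_PAIR_CLASS = {
    ("+", "-"): "DEL",
    ("-", "+"): "DUP",
    ("+", "+"): "h2hINV",
    ("-", "-"): "t2tINV",
}


class GenomeError(ValueError):
    """Raised for records inconsistent with the genome build or each other."""


@dataclass(frozen=True)
class GenomeBuild:
    """Ordered chromosome names and lengths."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise GenomeError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise GenomeError("duplicate chromosome names")
        if any(l <= 0 for l in self.chrom_lengths):
            raise GenomeError("chromosome lengths must be positive")

    @classmethod
    def from_dict(cls, lengths: dict[str, int]) -> "GenomeBuild":
        return cls(tuple(lengths), tuple(lengths.values()))

    def length(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[self.chrom_names.index(chrom)]
        except ValueError:
            raise GenomeError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_names

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))


@dataclass(frozen=True, order=True)
class Breakend:
    """One side of a rearrangement junction."""

    chrom: str
    pos: int
    side: str  # "+" joins sequence left of pos, "-" joins sequence right of pos

    def __post_init__(self) -> None:
        if self.side not in ("+", "-"):
            raise GenomeError(f"breakend side must be '+' or '-', got {self.side!r}")
        if self.pos < 0:
            raise GenomeError(f"negative breakend position {self.pos}")


def classify_sv_type(bnd1: Breakend, bnd2: Breakend) -> str:
    """Orientation class of the junction formed by two breakends.

    Different chromosomes give ``TRA``; otherwise breakends are ordered by
    position (ties: ``+`` before ``-``) and the side pair is looked up in the
    orientation table. Equal positions with identical sides describe a
    degenerate junction and raise :class:`GenomeError`.
    """
    if bnd1.chrom != bnd2.chrom:
        return "TRA"
    if bnd1.pos == bnd2.pos and bnd1.side == bnd2.side:
        raise GenomeError(
            f"degenerate junction: identical breakends {bnd1.chrom}:{bnd1.pos}:{bnd1.side}"
        )
    lo, hi = order_breakends(bnd1, bnd2)
    return _SIDE_PAIR_CLASS[(lo.side, hi.side)]


def order_breakends(bnd1: Breakend, bnd2: Breakend) -> tuple[Breakend, Breakend]:
    """Canonical (low, high) ordering: by chrom, then pos, then '+' before '-'."""
    key = lambda b: (b.chrom, b.pos, 0 if b.side == "+" else 1)
    return (bnd1, bnd2) if key(bnd1) <= key(bnd2) else (bnd2, bnd1)


@dataclass(frozen=True)
class SVRecord:
    """A rearrangement junction: two oriented breakends plus a class label.

    Use :func:`make_sv` to construct records with canonical breakend ordering
    and a consistent ``sv_class``.
    """

    id: str
    bnd1: Breakend
    bnd2: Breakend
    sv_class: str

    @property
    def chrom(self) -> str:
        """Chromosome of an intrachromosomal record."""
        if self.sv_class == "TRA":
            raise GenomeError("TRA record spans two chromosomes")
        return self.bnd1.chrom

    @property
    def footprint(self) -> tuple[int, int]:
        """[min pos, max pos] of an intrachromosomal record."""
        if self.sv_class == "TRA":
            raise GenomeError("TRA record has no single-chromosome footprint")
        return (self.bnd1.pos, self.bnd2.pos)

    @property
    def is_intra(self) -> bool:
        return self.sv_class != "TRA"

    def breakends(self) -> tuple[Breakend, Breakend]:
        return (self.bnd1, self.bnd2)


def make_sv(id: str, bnd1: Breakend, bnd2: Breakend) -> SVRecord:
    """Build an :class:`SVRecord` with canonical ordering and derived class."""
    sv_class = classify_sv_type(bnd1, bnd2)
    lo, hi = order_breakends(bnd1, bnd2)
    return SVRecord(id=id, bnd1=lo, bnd2=hi, sv_class=sv_class)


@dataclass(frozen=True)
class CNSegment:
    """A genomic interval with total (and optionally minor) copy number."""

    chrom: str
    start: int
    end: int
    total_cn: int
    minor_cn: int | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise GenomeError(
                f"CN segment {self.chrom}:{self.start}-{self.end} has start >= end"
            )
        if self.total_cn < 0:
            raise GenomeError(f"negative total copy number {self.total_cn}")
        if self.minor_cn is not None:
            if self.minor_cn < 0:
                raise GenomeError(f"negative minor copy number {self.minor_cn}")
            if self.minor_cn > self.total_cn:
                raise GenomeError(
                    f"minor CN {self.minor_cn} exceeds total CN {self.total_cn}"
                )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneRecord:
    """A gene interval with strand and an optional driver flag."""

    chrom: str
    start: int
    end: int
    strand: str
    name: str
    is_driver: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise GenomeError(f"gene {self.name!r} has start >= end")
        if self.strand not in ("+", "-"):
            raise GenomeError(f"gene strand must be '+' or '-', got {self.strand!r}")
        if not self.name:
            raise GenomeError("gene name must be non-empty")


@dataclass
class SampleData:
    """All per-sample inputs the caller consumes."""

    sample_id: str
    svs: list[SVRecord] = field(default_factory=list)
    cn: list[CNSegment] = field(default_factory=list)
    genome: GenomeBuild | None = None

    def __post_init__(self) -> None:
        if self.genome is None:
            return
        for sv in self.svs:
            for bnd in sv.breakends():
                if bnd.chrom not in self.genome:
                    raise GenomeError(
                        f"SV {sv.id}: chromosome {bnd.chrom!r} not in genome build"
                    )
                if bnd.pos > self.genome.length(bnd.chrom):
                    raise GenomeError(
                        f"SV {sv.id}: position {bnd.pos} beyond {bnd.chrom} length"
                    )
        for seg in self.cn:
            if seg.chrom not in self.genome:
                raise GenomeError(
                    f"CN segment chromosome {seg.chrom!r} not in genome build"
                )


def validate_cn_segments(segments: list[CNSegment]) -> list[CNSegment]:
    """Sort by (chrom, start) and verify per-chromosome non-overlap."""
    out = sorted(segments, key=lambda s: (s.chrom, s.start))
    for a, b in zip(out, out[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise GenomeError(
                f"overlapping CN segments on {a.chrom}: "
                f"[{a.start},{a.end}) and [{b.start},{b.end})"
            )
    return out


__all__ = [
    "SV_CLASSES",
    "GenomeError",
    "GenomeBuild",
    "Breakend",
    "SVRecord",
    "CNSegment",
    "GeneRecord",
    "SampleData",
    "classify_sv_type",
    "order_breakends",
    "make_sv",
    "validate_cn_segments",
]
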
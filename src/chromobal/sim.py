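"""Mechanistic simulator: micronucleus shattering, inheritance, rejoining.

Generative model
----------------
A missegregated chromosome trapped in a micronucleus is pulverized within a
shatter region into ``K + 1`` fragments (K uniform integer breakpoints).
Each fragment is then lost to the cytoplasm with probability ``p_loss``;
survivors are partitioned between the two daughter nuclei:

* ``clustered`` — fragments remain tethered together through mitosis and all
  segregate to one daughter (daughter A), which reassembles them into a
  derivative chromosome by random order and orientation: a cluster of
  interleaved rearrangements with *no* copy-number loss (balanced
  chromothripsis) when ``p_loss`` is 0;
* ``dispersed`` — fragments scatter and each goes to either daughter with
  probability 1/2; daughter A's derivative then lacks roughly half the
  region, producing the canonical two-state oscillating CN profile;
* ``chromoplexy`` — a negative control: one breakpoint on each of ``m``
  chromosomes, cyclically joined into a chain of translocations with flat
  copy number.

Sequencing-like output (BEDPE junctions + CN segment TSV) is derived from
daughter A's derivative only. Fragments are single-copy (no replicative
duplication): DUP-class junctions arise purely from reordering, as in
balanced events where no CN gain is required.

RNG stream order (one ``numpy`` Generator per sample, fully determined by
the seed): shatter breakpoints, loss draws, daughter draws, fragment
permutation, orientation flips.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .genome import Breakend, CNSegment, GenomeBuild, SVRecord, make_sv
from . import io as cio

MODES = ("clustered", "dispersed", "chromoplexy")

# Focal chromosome: one human Y (GRCh38 length), the classic single-copy
# model for micronucleus-driven shattering; partner chromosomes only host
# chromoplexy chain breakpoints.
DEFAULT_CHROM = "chrY"
DEFAULT_CHROM_LENGTH = 57_227_415
DEFAULT_REGION = (15_000_000, 45_000_000)  # ~30 Mb shatter region
PARTNER_CHROMS = {"chr1": 100_000_000, "chr2": 100_000_000, "chr3": 100_000_000,
                  "chr4": 100_000_000, "chr5": 100_000_000}


@dataclass(frozen=True)
class Fragment:
    """A piece of the shattered region, with inheritance fate and orientation."""

    ref_start: int
    ref_end: int
    fate: str = "daughterA"          # daughterA | daughterB | cytoplasm
    orientation: str = "forward"     # set at reassembly; forward | reverse

    def __post_init__(self) -> None:
        if self.ref_start >= self.ref_end:
            raise ValueError("fragment ref_start must be < ref_end")

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated sample."""

    mode: str = "clustered"
    chrom: str = DEFAULT_CHROM
    chrom_length: int = DEFAULT_CHROM_LENGTH
    shatter_region: tuple[int, int] = DEFAULT_REGION
    n_breakpoints: int = 10
    p_loss: float = 0.0
    background_ploidy: int = 1
    n_chromoplexy_chroms: int = 3
    loss_threshold: float = 0.01     # truth-label boundary, mirrors the caller
    anchor_first_fragment: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if not 0.0 <= self.p_loss <= 1.0:
            raise ValueError("p_loss must be in [0, 1]")
        if self.n_breakpoints < 0:
            raise ValueError("n_breakpoints must be >= 0")
        start, end = self.shatter_region
        if not (0 <= start < end <= self.chrom_length):
            raise ValueError("shatter_region must lie within the chromosome")
        if self.mode == "chromoplexy" and self.n_chromoplexy_chroms < 3:
            raise ValueError("chromoplexy mode needs >= 3 chromosomes")

    def genome(self) -> GenomeBuild:
        lengths = {self.chrom: self.chrom_length}
        if self.mode == "chromoplexy":
            lengths.update(PARTNER_CHROMS)
        return GenomeBuild.from_dict(lengths)


@dataclass
class SimSample:
    """Simulator output with ground truth."""

    sample_id: str
    config: SimConfig
    fragments: list[Fragment]
    derivative: list[Fragment]       # ordered, oriented daughter-A fragments
    svs: list[SVRecord]
    cn: list[CNSegment]
    truth_label: str                 # balanced | canonical | chromoplexy
    loss_fraction: float             # region fraction absent from the derivative
    partition_ratio: float | None    # None when no fragment reaches a nucleus


def shatter(config: SimConfig, rng: np.random.Generator) -> list[Fragment]:
    """Draw K distinct uniform breakpoints; return K+1 tiling fragments."""
    start, end = config.shatter_region
    k = config.n_breakpoints
    if k > end - start - 1:
        raise ValueError(f"{k} breakpoints do not fit in a {end - start} bp region")
    cuts: set[int] = set()
    while len(cuts) < k:  # rejection-sample distinct cut sites
        cuts.update(int(c) for c in rng.integers(start + 1, end, size=k - len(cuts)))
    bounds = [start, *sorted(cuts), end]
    return [Fragment(a, b) for a, b in zip(bounds, bounds[1:])]


def assign_fragments(
    fragments: list[Fragment], mode: str, p_loss: float, rng: np.random.Generator
) -> list[Fragment]:
    """Assign each fragment a fate: cytoplasmic loss, then daughter choice.

    Loss draws are made for every fragment, then daughter draws for every
    fragment (also for lost ones, to keep the RNG stream aligned across
    ``p_loss`` values); lost fragments keep fate ``cytoplasm``.
    """
    if mode not in ("clustered", "dispersed"):
        raise ValueError("assign_fragments handles clustered/dispersed modes only")
    n = len(fragments)
    lost = rng.random(n) < p_loss
    to_b = rng.random(n) < 0.5 if mode == "dispersed" else np.zeros(n, dtype=bool)
    out = []
    for frag, is_lost, is_b in zip(fragments, lost, to_b):
        fate = "cytoplasm" if is_lost else ("daughterB" if is_b else "daughterA")
        out.append(replace(frag, fate=fate))
    return out


def _junction_breakends(left: Fragment, right: Fragment, chrom: str) -> tuple[Breakend, Breakend]:
    """Breakends of the junction joining left's right end to right's left end."""
    if left.orientation == "forward":
        b1 = Breakend(chrom, left.ref_end, "+")
    else:
        b1 = Breakend(chrom, left.ref_start, "-")
    if right.orientation == "forward":
        b2 = Breakend(chrom, right.ref_start, "-")
    else:
        b2 = Breakend(chrom, right.ref_end, "+")
    return b1, b2


def _reference_adjacent(left: Fragment, right: Fragment) -> bool:
    """True when the pair reconstructs contiguous reference sequence."""
    if left.orientation != right.orientation:
        return False
    if left.orientation == "forward":
        return left.ref_end == right.ref_start
    return left.ref_start == right.ref_end


def derive_junctions(
    derivative: list[Fragment], chrom: str = DEFAULT_CHROM, sv_prefix: str = "sv"
) -> list[SVRecord]:
    """Junctions implied by an ordered, oriented derivative chromosome.

    One junction per adjacency, except reference-adjacent co-oriented pairs
    (contiguous sequence, no breakpoint).
    """
    svs: list[SVRecord] = []
    for left, right in zip(derivative, derivative[1:]):
        if _reference_adjacent(left, right):
            continue
        b1, b2 = _junction_breakends(left, right, chrom)
        svs.append(make_sv(f"{sv_prefix}{len(svs) + 1}", b1, b2))
    return svs


def reassemble_and_derive_svs(
    retained: list[Fragment],
    rng: np.random.Generator,
    chrom: str = DEFAULT_CHROM,
    anchor_first: bool = False,
    sv_prefix: str = "sv",
) -> tuple[list[Fragment], list[SVRecord]]:
    """Random-order, random-orientation reassembly and derived junctions.

    Fragments are permuted uniformly and each is independently reversed with
    probability 1/2 (``anchor_first`` pins the first reference fragment
    forward at the head, mimicking a retained centric end). Each derivative
    adjacency yields one junction unless the pair is reference-adjacent and
    co-oriented (contiguous sequence, no breakpoint).
    """
    if not retained:
        raise ValueError("cannot reassemble an empty fragment set")
    n = len(retained)
    order = rng.permutation(n)
    flips = rng.random(n) < 0.5
    if anchor_first:
        head = int(np.where(order == 0)[0][0])
        order = np.concatenate(([0], np.delete(order, head)))
        flips[0] = False
    derivative = [
        replace(retained[i], orientation="reverse" if flip else "forward")
        for i, flip in zip(order, flips)
    ]
    return derivative, derive_junctions(derivative, chrom, sv_prefix)


def derive_cn_profile(
    fragments: list[Fragment], config: SimConfig
) -> list[CNSegment]:
    """Copy-number segments implied by fragment retention in the derivative.

    Outside the shatter region CN equals ``background_ploidy``; inside, a base
    covered by a retained (daughter A) fragment keeps that ploidy while a lost
    fragment's bases drop by one copy. Adjacent equal-CN segments are merged.
    """
    chrom, length = config.chrom, config.chrom_length
    start, end = config.shatter_region
    ploidy = config.background_ploidy
    points: list[tuple[int, int, int]] = []
    if start > 0:
        points.append((0, start, ploidy))
    for frag in sorted(fragments, key=lambda f: f.ref_start):
        cn = ploidy if frag.fate == "daughterA" else ploidy - 1
        points.append((frag.ref_start, frag.ref_end, max(cn, 0)))
    if end < length:
        points.append((end, length, ploidy))
    merged: list[CNSegment] = []
    for s, e, cn in points:
        if merged and merged[-1].end == s and merged[-1].total_cn == cn:
            merged[-1] = CNSegment(chrom, merged[-1].start, e, cn)
        else:
            merged.append(CNSegment(chrom, s, e, cn))
    return merged


def partition_ratio(fragments: list[Fragment]) -> float:
    """Lower-daughter over higher-daughter summed fragment length.

    Cytoplasmic fragments are excluded (the nuclear-signal readout). A fully
    one-sided segregation returns 0 (the "0:1" ratio); an even split returns
    1. All-cytoplasmic input is an error.
    """
    la = sum(f.length for f in fragments if f.fate == "daughterA")
    lb = sum(f.length for f in fragments if f.fate == "daughterB")
    if la == 0 and lb == 0:
        raise ValueError("no fragment reached either daughter nucleus")
    return min(la, lb) / max(la, lb)


def _simulate_chromoplexy(
    config: SimConfig, rng: np.random.Generator
) -> tuple[list[SVRecord], list[CNSegment]]:
    """Cyclic chain of translocations: one breakpoint per chromosome, flat CN."""
    genome = config.genome()
    chroms = [config.chrom] + [
        c for c in PARTNER_CHROMS if c != config.chrom
    ][: config.n_chromoplexy_chroms - 1]
    breakpoints = [
        (c, int(rng.integers(1, genome.length(c)))) for c in chroms
    ]
    svs = []
    m = len(breakpoints)
    for i in range(m):
        c1, p1 = breakpoints[i]
        c2, p2 = breakpoints[(i + 1) % m]
        # chain joins the left flank of one break to the right flank of the next
        svs.append(make_sv(f"tra{i + 1}", Breakend(c1, p1, "+"), Breakend(c2, p2, "-")))
    cn = [
        CNSegment(c, 0, genome.length(c), config.background_ploidy if c == config.chrom else 2)
        for c in genome.chrom_names
    ]
    return svs, cn


def simulate_sample(config: SimConfig, sample_id: str = "sample") -> SimSample:
    """Run the full generative model for one sample."""
    rng = np.random.default_rng(config.seed)
    if config.mode == "chromoplexy":
        svs, cn = _simulate_chromoplexy(config, rng)
        return SimSample(
            sample_id=sample_id, config=config, fragments=[], derivative=[],
            svs=svs, cn=cn, truth_label="chromoplexy", loss_fraction=0.0,
            partition_ratio=None,
        )

    fragments = shatter(config, rng)
    fragments = assign_fragments(fragments, config.mode, config.p_loss, rng)
    retained = [f for f in fragments if f.fate == "daughterA"]
    region_len = config.shatter_region[1] - config.shatter_region[0]
    retained_len = sum(f.length for f in retained)
    loss_fraction = (region_len - retained_len) / region_len
    if retained:
        derivative, svs = reassemble_and_derive_svs(
            retained, rng, chrom=config.chrom, anchor_first=config.anchor_first_fragment
        )
    else:
        derivative, svs = [], []
    cn = derive_cn_profile(fragments, config)
    try:
        ratio = partition_ratio(fragments)
    except ValueError:
        ratio = None
    truth = "balanced" if loss_fraction < config.loss_threshold else "canonical"
    return SimSample(
        sample_id=sample_id, config=config, fragments=fragments,
        derivative=derivative, svs=svs, cn=cn, truth_label=truth,
        loss_fraction=loss_fraction, partition_ratio=ratio,
    )


def write_sample(sample: SimSample, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write sample.bedpe, sample.cn.tsv and sample.truth.json; return paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "bedpe": str(out / f"{sample.sample_id}.bedpe"),
        "cn": str(out / f"{sample.sample_id}.cn.tsv"),
        "truth": str(out / f"{sample.sample_id}.truth.json"),
    }
    cio.write_bedpe(sample.svs, paths["bedpe"])
    cio.write_cn_segments(sample.cn, paths["cn"])
    cfg = {k: (list(v) if isinstance(v, tuple) else v)
           for k, v in vars(sample.config).items()}
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "sample_id": sample.sample_id,
                "config": cfg,
                "truth_label": sample.truth_label,
                "loss_fraction": sample.loss_fraction,
                "partition_ratio": sample.partition_ratio,
                "n_svs": len(sample.svs),
                "n_fragments": len(sample.fragments),
            },
            fh,
            indent=2,
        )
        fh.write("\n")
    return paths


def simulate_cohort(
    configs: list[tuple[str, SimConfig]], out_dir: str | os.PathLike
) -> "pd.DataFrame":
    """Simulate and write a cohort; returns (and writes) a manifest table."""
    import pandas as pd

    rows = []
    genome: GenomeBuild | None = None
    for sample_id, config in configs:
        sample = simulate_sample(config, sample_id)
        paths = write_sample(sample, out_dir)
        g = config.genome().as_dict()
        genome = GenomeBuild.from_dict(
            {**(genome.as_dict() if genome else {}), **g}
        )
        rows.append(
            {
                "sample": sample_id,
                "mode": config.mode,
                "truth_label": sample.truth_label,
                "loss_fraction": sample.loss_fraction,
                "sv": paths["bedpe"],
                "cn": paths["cn"],
                "truth": paths["truth"],
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(Path(out_dir) / "manifest.tsv", sep="\t", index=False)
    if genome is not None:
        cio.write_genome(genome, Path(out_dir) / "genome.tsv")
    return manifest


__all__ = [
    "MODES",
    "Fragment",
    "SimConfig",
    "SimSample",
    "shatter",
    "assign_fragments",
    "derive_junctions",
    "reassemble_and_derive_svs",
    "derive_cn_profile",
    "partition_ratio",
    "simulate_sample",
    "write_sample",
    "simulate_cohort",
]
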
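"""Readers and writers for the formats the pipeline touches.

BEDPE (10 columns), VCF v4.2 breakend (BND) records, CN segment TSV, BED6 and
GFF3 gene models, chromosome-sizes TSV. BEDPE and BED are native 0-based
half-open; VCF positions are converted to the internal 0-based convention.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import pandas as pd

from .genome import (
    Breakend,
    CNSegment,
    GeneRecord,
    GenomeBuild,
    GenomeError,
    SVRecord,
    make_sv,
    validate_cn_segments,
)

logger = logging.getLogger(__name__)

CN_COLUMNS = ["chrom", "start", "end", "total_cn", "minor_cn"]


def _check_chrom(chrom: str, genome: GenomeBuild | None, context: str) -> None:
    if genome is not None and chrom not in genome:
        raise GenomeError(f"{context}: unknown chromosome {chrom!r}")


# ---------------------------------------------------------------------------
# BEDPE
# ---------------------------------------------------------------------------

def read_bedpe_svs(path: str | os.PathLike, genome: GenomeBuild | None = None) -> list[SVRecord]:
    """Read SV junctions from a >=10-column BEDPE file.

    Columns: chrom1 start1 end1 chrom2 start2 end2 name score strand1 strand2.
    The breakend position is the *start* of each interval (point-resolved
    calls). Records are canonically ordered and classified on construction.
    Duplicate names are tolerated and re-keyed to stay unique.
    """
    svs: list[SVRecord] = []
    seen: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise GenomeError(
                    f"{path}:{lineno}: BEDPE needs >=10 columns "
                    f"(chrom1,start1,end1,chrom2,start2,end2,name,score,strand1,strand2), "
                    f"got {len(fields)}"
                )
            c1, s1, e1, c2, s2, e2, name, _score, strand1, strand2 = fields[:10]
            _check_chrom(c1, genome, f"{path}:{lineno}")
            _check_chrom(c2, genome, f"{path}:{lineno}")
            s1, e1, s2, e2 = int(s1), int(e1), int(s2), int(e2)
            if s1 > e1 or s2 > e2:
                raise GenomeError(f"{path}:{lineno}: interval start > end")
            if strand1 not in ("+", "-") or strand2 not in ("+", "-"):
                raise GenomeError(
                    f"{path}:{lineno}: missing or invalid strand columns "
                    f"({strand1!r}, {strand2!r})"
                )
            if name in seen:
                seen[name] += 1
                uid = f"{name}.{seen[name]}"
            else:
                seen[name] = 0
                uid = name
            svs.append(
                make_sv(uid, Breakend(c1, s1, strand1), Breakend(c2, s2, strand2))
            )
    return svs


def write_bedpe(svs: list[SVRecord], path: str | os.PathLike) -> None:
    """Write SV records as 10-column BEDPE ('.' score, 1-bp intervals)."""
    with open(path, "w") as fh:
        for sv in svs:
            b1, b2 = sv.bnd1, sv.bnd2
            fh.write(
                "\t".join(
                    [
                        b1.chrom, str(b1.pos), str(b1.pos + 1),
                        b2.chrom, str(b2.pos), str(b2.pos + 1),
                        sv.id, ".", b1.side, b2.side,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# VCF breakends
# ---------------------------------------------------------------------------

def _bnd_side_from_alt(alt: str) -> str:
    """Side of the breakend carried by a BND ALT string.

    ``t[p[`` / ``t]p]`` (inserted sequence before the bracket) mean the local
    sequence left of POS is retained -> side "+"; ``]p]t`` / ``[p[t`` mean the
    sequence right of POS is retained -> side "-".
    """
    if alt[0] in "[]":
        return "-"
    if alt[-1] in "[]":
        return "+"
    raise GenomeError(f"malformed BND ALT {alt!r}")


def read_vcf_bnd(path: str | os.PathLike, genome: GenomeBuild | None = None) -> list[SVRecord]:
    """Read breakend (BND) records from a VCF and pair mates into SVRecords.

    Mates are paired through the MATEID INFO field; each pair yields one
    record. VCF 1-based positions are shifted by -1 onto the internal
    convention. Non-BND records are skipped (counted in the log); an orphan
    mate is an error.
    """
    import pysam

    bnds: dict[str, tuple[str, int, str, str]] = {}  # id -> (chrom, pos0, side, mateid)
    skipped = 0
    with pysam.VariantFile(os.fspath(path)) as vf:
        for rec in vf:
            alt = rec.alts[0] if rec.alts else ""
            if "[" not in alt and "]" not in alt:
                skipped += 1
                continue
            mateid = rec.info.get("MATEID")
            if isinstance(mateid, tuple):
                mateid = mateid[0]
            if mateid is None:
                raise GenomeError(f"{path}: BND record {rec.id!r} lacks MATEID")
            _check_chrom(rec.chrom, genome, f"{path} record {rec.id!r}")
            bnds[rec.id] = (rec.chrom, rec.pos - 1, _bnd_side_from_alt(alt), mateid)
    if skipped:
        logger.info("%s: skipped %d non-BND records", path, skipped)

    svs: list[SVRecord] = []
    done: set[str] = set()
    orphans: list[str] = []
    for rid, (chrom, pos, side, mateid) in bnds.items():
        if rid in done:
            continue
        mate = bnds.get(mateid)
        if mate is None or mate[3] != rid:
            orphans.append(rid)
            continue
        mchrom, mpos, mside, _ = mate
        done.update((rid, mateid))
        svs.append(
            make_sv(rid.rsplit("_", 1)[0] if rid.endswith(("_1", "_2")) else rid,
                    Breakend(chrom, pos, side), Breakend(mchrom, mpos, mside))
        )
    if orphans:
        raise GenomeError(f"{path}: unpaired BND mates: {sorted(orphans)}")
    return svs


# ---------------------------------------------------------------------------
# Copy-number segments
# ---------------------------------------------------------------------------

def read_cn_segments(path: str | os.PathLike, genome: GenomeBuild | None = None) -> list[CNSegment]:
    """Read a CN segment TSV (header chrom/start/end/total_cn[/minor_cn]).

    Segments are returned sorted by (chrom, start); overlapping segments on
    one chromosome or negative copy numbers are errors.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"chrom", "start", "end", "total_cn"} - set(df.columns)
    if missing:
        raise GenomeError(f"{path}: missing CN columns {sorted(missing)}")
    has_minor = "minor_cn" in df.columns
    segments = []
    for row in df.itertuples(index=False):
        _check_chrom(row.chrom, genome, str(path))
        minor = None
        if has_minor and not pd.isna(row.minor_cn):
            minor = int(row.minor_cn)
        segments.append(
            CNSegment(row.chrom, int(row.start), int(row.end), int(row.total_cn), minor)
        )
    return validate_cn_segments(segments)


def write_cn_segments(segments: list[CNSegment], path: str | os.PathLike) -> None:
    rows = [
        {
            "chrom": s.chrom,
            "start": s.start,
            "end": s.end,
            "total_cn": s.total_cn,
            "minor_cn": "" if s.minor_cn is None else s.minor_cn,
        }
        for s in segments
    ]
    pd.DataFrame(rows, columns=CN_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genes
# ---------------------------------------------------------------------------

def read_genes(
    path: str | os.PathLike,
    genome: GenomeBuild | None = None,
    drivers: str | os.PathLike | None = None,
) -> list[GeneRecord]:
    """Read gene models from BED6 or GFF3 ('gene'-type records only).

    ``drivers`` is an optional text file of gene symbols (one per line)
    setting ``is_driver`` by exact name match. Records on chromosomes absent
    from the genome build are dropped with a logged count.
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        genes = _read_genes_gff3(path)
    else:
        genes = _read_genes_bed6(path)
    if genome is not None:
        kept = [g for g in genes if g.chrom in genome]
        if len(kept) < len(genes):
            logger.warning(
                "%s: dropped %d genes on chromosomes absent from the genome build",
                path, len(genes) - len(kept),
            )
        genes = kept
    if drivers is not None:
        names = {
            line.strip() for line in open(drivers) if line.strip() and not line.startswith("#")
        }
        genes = [
            GeneRecord(g.chrom, g.start, g.end, g.strand, g.name, g.name in names)
            for g in genes
        ]
    return genes


def _read_genes_bed6(path: Path) -> list[GeneRecord]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise GenomeError(f"{path}:{lineno}: BED6 needs 6 columns, got {len(fields)}")
            chrom, start, end, name, _score, strand = fields[:6]
            genes.append(GeneRecord(chrom, int(start), int(end), strand, name))
    return genes


def _read_genes_gff3(path: Path) -> list[GeneRecord]:
    import gffutils

    db = gffutils.create_db(
        os.fspath(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for feat in db.features_of_type("gene"):
        name = (feat.attributes.get("Name") or feat.attributes.get("ID") or [feat.id])[0]
        # GFF3 is 1-based inclusive; convert to 0-based half-open
        genes.append(GeneRecord(feat.seqid, feat.start - 1, feat.end, feat.strand, name))
    return genes


# ---------------------------------------------------------------------------
# Misc
# ---------------------------------------------------------------------------

def read_genome(path: str | os.PathLike) -> GenomeBuild:
    """Read a two-column chromosome-sizes TSV (name, length)."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, size = line.split("\t")[:2]
            lengths[name] = int(size)
    return GenomeBuild.from_dict(lengths)


def write_genome(genome: GenomeBuild, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, size in genome.as_dict().items():
            fh.write(f"{name}\t{size}\n")


def read_bed_regions(path: str | os.PathLike) -> list[tuple[str, int, int]]:
    """Read plain BED intervals (e.g. chromoplexy exclusion regions)."""
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GenomeError(f"{path}:{lineno}: BED needs >=3 columns")
            regions.append((fields[0], int(fields[1]), int(fields[2])))
    return regions


__all__ = [
    "read_bedpe_svs",
    "write_bedpe",
    "read_vcf_bnd",
    "read_cn_segments",
    "write_cn_segments",
    "read_genes",
    "read_genome",
    "write_genome",
    "read_bed_regions",
]
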
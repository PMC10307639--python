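"""End-to-end orchestration: read inputs, cluster, call, annotate, report.

The pipeline is deterministic: rerunning with an identical configuration
produces bit-identical tables. Every criterion evaluation is logged per
cluster, giving an auditable trail in place of manual plot review.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as cio
from .caller import (
    CallThresholds,
    ChromothripsisCall,
    SampleSummary,
    call_cluster,
    calls_to_table,
    summarize_sample,
)
from .clustering import detect_clusters
from .cn_metrics import CNProfile
from .gene_impact import (
    disrupted_genes,
    fusion_candidates,
    fusions_to_table,
    impacts_to_table,
)
from .genome import GeneRecord, GenomeBuild, SampleData

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs, thresholds and output location for a pipeline run."""

    manifest: str | None = None          # TSV: sample, sv, cn columns
    sv_path: str | None = None           # single-sample alternative
    cn_path: str | None = None
    sample_id: str = "sample"
    genome_path: str | None = None
    genes_path: str | None = None
    drivers_path: str | None = None
    chromoplexy_bed: str | None = None
    out_dir: str = "chromobal_out"
    thresholds: CallThresholds = field(default_factory=CallThresholds)
    plot: bool = False

    def sample_table(self) -> pd.DataFrame:
        if self.manifest is not None:
            df = pd.read_csv(self.manifest, sep="\t", dtype=str)
            missing = {"sample", "sv", "cn"} - set(df.columns)
            if missing:
                raise ValueError(f"manifest missing columns {sorted(missing)}")
            return df[["sample", "sv", "cn"]]
        if self.sv_path is None or self.cn_path is None:
            raise ValueError("provide either a manifest or sv_path + cn_path")
        return pd.DataFrame(
            [{"sample": self.sample_id, "sv": self.sv_path, "cn": self.cn_path}]
        )


@dataclass
class SampleResult:
    sample: SampleData
    calls: list[ChromothripsisCall]
    summary: SampleSummary


def call_sample(
    sample: SampleData,
    thresholds: CallThresholds = CallThresholds(),
    chromoplexy_regions: list[tuple[str, int, int]] | None = None,
) -> SampleResult:
    """Cluster one sample's SVs and classify every cluster."""
    clusters = detect_clusters(
        sample.svs, min_sv=thresholds.min_sv, gap_max=thresholds.gap_max
    )
    calls = []
    for cluster in clusters:
        try:
            profile = CNProfile.from_segments(sample.cn, cluster.chrom)
        except ValueError:  # chromosome without any CN data
            call = ChromothripsisCall(
                cluster, "rejected", ["uncallable_span"],
                {"n_intra": cluster.n_intra, "interleave_frac": cluster.interleave_frac,
                 "chromoplexy_evaluated": chromoplexy_regions is not None,
                 "loss_frac": None, "gain_frac": None, "uncovered_frac": 1.0,
                 "modal_cn": None, "oscillation_run": None, "n_tra_in_span": None},
            )
            calls.append(call)
            continue
        call = call_cluster(
            cluster, sample.svs, profile, chromoplexy_regions, thresholds
        )
        logger.info(
            "%s %s:%d-%d n_intra=%d tra_in_span=%s loss=%s -> %s %s",
            sample.sample_id, cluster.chrom, cluster.span_start, cluster.span_end,
            cluster.n_intra, call.metrics.get("n_tra_in_span"),
            call.metrics.get("loss_frac"), call.classification,
            ";".join(call.reject_reasons) or "-",
        )
        calls.append(call)
    return SampleResult(sample, calls, summarize_sample(calls, sample.sample_id))


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run the cohort: per-sample calling, gene annotation, report tables.

    Writes calls.tsv/calls.json, summary.tsv, impact.tsv, fusions.tsv and a
    run_manifest.json echoing all parameters; returns the tables keyed by
    name. Raises before producing output when a required input is missing; a
    sample whose files fail to parse is skipped with a logged reason and
    reported in the manifest (a nonzero exit is the CLI's job).
    """
    table = config.sample_table()
    for col in ("sv", "cn"):
        for path in table[col]:
            if not Path(path).exists():
                raise FileNotFoundError(f"missing input file {path}")
    genome = cio.read_genome(config.genome_path) if config.genome_path else None
    genes: list[GeneRecord] = []
    if config.genes_path:
        genes = cio.read_genes(config.genes_path, genome, config.drivers_path)
    regions = (
        cio.read_bed_regions(config.chromoplexy_bed) if config.chromoplexy_bed else None
    )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    call_tables, summary_rows, impact_tables, fusion_tables = [], [], [], []
    failures: list[str] = []
    for row in table.itertuples(index=False):
        try:
            sample = SampleData(
                sample_id=row.sample,
                svs=cio.read_bedpe_svs(row.sv, genome),
                cn=cio.read_cn_segments(row.cn, genome),
                genome=genome,
            )
        except Exception as exc:  # parse failure: skip sample, keep cohort
            logger.error("sample %s skipped: %s", row.sample, exc)
            failures.append(row.sample)
            continue
        result = call_sample(sample, config.thresholds, regions)
        if result.calls:
            call_tables.append(calls_to_table(result.calls, row.sample))
        s = result.summary
        summary_rows.append(
            {
                "sample": s.sample_id,
                "n_clusters": s.n_clusters,
                "n_balanced": s.n_balanced,
                "n_canonical_like": s.n_canonical_like,
                "n_rejected": s.n_rejected,
                "balanced_chromosomes": ",".join(s.balanced_chromosomes),
                "multi_chromosome": s.multi_chromosome,
            }
        )
        balanced = [c for c in result.calls if c.is_balanced]
        if genes and balanced:
            impacts = disrupted_genes(balanced, genes, config.thresholds.gene_pad)
            impact_table = impacts_to_table(impacts, row.sample)
            if not impact_table.empty:
                impact_tables.append(impact_table)
            fusion_table = fusions_to_table(fusion_candidates(balanced, genes), row.sample)
            if not fusion_table.empty:
                fusion_tables.append(fusion_table)
        if config.plot:
            from .plot import plot_call

            for i, call in enumerate(balanced):
                plot_call(
                    call, sample.cn,
                    out / f"{row.sample}.{call.cluster.chrom}.{i}.svg",
                )

    tables = {
        "calls": pd.concat(call_tables, ignore_index=True)
        if call_tables else calls_to_table([]),
        "summary": pd.DataFrame(
            summary_rows,
            columns=["sample", "n_clusters", "n_balanced", "n_canonical_like",
                     "n_rejected", "balanced_chromosomes", "multi_chromosome"],
        ),
        "impact": pd.concat(impact_tables, ignore_index=True)
        if impact_tables else impacts_to_table([]),
        "fusions": pd.concat(fusion_tables, ignore_index=True)
        if fusion_tables else fusions_to_table([]),
    }
    tables["calls"].to_csv(out / "calls.tsv", sep="\t", index=False)
    tables["summary"].to_csv(out / "summary.tsv", sep="\t", index=False)
    tables["impact"].to_csv(out / "impact.tsv", sep="\t", index=False)
    tables["fusions"].to_csv(out / "fusions.tsv", sep="\t", index=False)
    with open(out / "calls.json", "w") as fh:
        json.dump(tables["calls"].to_dict(orient="records"), fh, indent=2, default=str)
        fh.write("\n")
    manifest = {
        "thresholds": vars(config.thresholds),
        "inputs": {
            "manifest": config.manifest, "sv": config.sv_path, "cn": config.cn_path,
            "genome": config.genome_path, "genes": config.genes_path,
            "drivers": config.drivers_path, "chromoplexy_bed": config.chromoplexy_bed,
        },
        "n_samples": int(len(table)),
        "failed_samples": failures,
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    if failures:
        raise RuntimeError(f"samples failed to parse: {failures}")
    return tables


__all__ = ["RunConfig", "SampleResult", "call_sample", "run_pipeline"]
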
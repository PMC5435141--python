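"""End-to-end orchestration of the short-intron discovery workflow.

Stage order: per-sample npIDR cutoff -> cross-sample pooling -> length
filter (10-70 nt) -> genomic-deletion screens -> pooled read-support cutoff
against unannotated long introns -> end/annotation/region classification ->
splicing efficiency -> folding -> IRE1 motif scan.  Each stage's surviving
record count is kept as a funnel for reporting.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import conservation, efficiency, folding, motifs
from .annotation import AnnotationModel
from .artifacts import apply_artifact_screens
from .classify import classify_records
from .conservation import NoQualifyingCutoff
from .junctions import GenomeRef, extract_intron_context
from .records import IntronRecord
from .reproducibility import NpidrCurve, choose_support_cutoff

logger = logging.getLogger("intronseek")


@dataclass
class PipelineConfig:
    npidr_threshold: float = 0.90
    npidr_max_cutoff: int = 50
    min_length: int = 10
    max_length: int = 70
    read_cutoff: int | None = None  # None = derive from the long-intron comparison
    read_cutoff_max: int = 50
    as_window: int = 50
    flank: int = 10
    folding_engine: str = "builtin"
    include_undefined_strand: bool = False


@dataclass
class PipelineResult:
    config: PipelineConfig
    npidr_curves: dict[str, NpidrCurve]
    sample_cutoffs: dict[str, int]
    funnel: dict[str, int]
    records: list[IntronRecord]          # final short-intron pool
    removed_records: list[IntronRecord]  # artifact-flagged
    read_cutoff: int
    cutoff_table: list[tuple[int, int, float]]
    profiles: dict[str, conservation.SupportProfile]
    efficiency_table: pd.DataFrame | None = None
    support_correlation: tuple | None = None  # (bin table, R, p)
    deltag_correlation: tuple | None = None
    motif_hits: list = field(default_factory=list)
    motif_searched: int = 0
    motif_expected: float = 0.0
    motif_pvalue: float = 1.0
    motif_boundary_hist: dict = field(default_factory=dict)
    motif_near_boundary: int = 0

    def summary(self) -> dict:
        canonical = sum(r.canonical for r in self.records)
        return {
            "funnel": self.funnel,
            "sample_cutoffs": dict(sorted(self.sample_cutoffs.items())),
            "read_cutoff": self.read_cutoff,
            "final_pool_size": len(self.records),
            "canonical": canonical,
            "non_canonical": len(self.records) - canonical,
            "support_R": None if self.support_correlation is None
            else self.support_correlation[1],
            "deltag_R": None if self.deltag_correlation is None
            else self.deltag_correlation[1],
            "ire1_observed": len(self.motif_hits),
            "ire1_expected": self.motif_expected,
            "ire1_pvalue": self.motif_pvalue,
            "ire1_near_boundary": self.motif_near_boundary,
        }


def run_pipeline(
    junctions_by_sample: Mapping[str, tuple],
    genome: GenomeRef,
    annotation: AnnotationModel,
    coverage: efficiency.TableCoverage | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run every stage on in-memory inputs.

    ``junctions_by_sample`` maps a sample (cell line) id to its pair of
    replicate junction lists.
    """
    cfg = config or PipelineConfig()
    funnel: dict[str, int] = {}
    funnel["junction_rows"] = sum(
        len(rep) for reps in junctions_by_sample.values() for rep in reps
    )

    # stage 1: per-sample npIDR support cutoffs
    curves: dict[str, NpidrCurve] = {}
    for sample_id in sorted(junctions_by_sample):
        rep_a, rep_b = junctions_by_sample[sample_id]
        curves[sample_id] = choose_support_cutoff(
            rep_a, rep_b, threshold=cfg.npidr_threshold,
            n_max=cfg.npidr_max_cutoff, sample_id=sample_id,
        )
    cutoffs = {s: c.chosen_cutoff for s, c in curves.items()}

    # stage 2: pool across samples
    aggregated = conservation.aggregate_junctions(junctions_by_sample, cutoffs)
    funnel["pooled_introns"] = len(aggregated)

    # stage 3: length filter and sequence extraction
    candidates: list[IntronRecord] = []
    n_boundary_dropped = 0
    for key in sorted(aggregated):
        entry = aggregated[key]
        if not (cfg.min_length <= entry.length <= cfg.max_length):
            continue
        rec = IntronRecord(
            chrom=entry.chrom, start=entry.start, end=entry.end,
            strand=entry.strand, samples_detected=entry.samples_detected,
            total_unique_reads=entry.total_unique_reads,
        )
        try:
            ctx = extract_intron_context(
                _junction_view(rec), genome, flank=cfg.flank
            )
        except (IndexError, KeyError):
            n_boundary_dropped += 1
            logger.warning("dropping %s: flanked interval outside chromosome",
                           rec.intron_id)
            continue
        rec.flank5, rec.intron_seq, rec.flank3 = ctx.flank5, ctx.intron, ctx.flank3
        candidates.append(rec)
    funnel["short_candidates"] = len(candidates)
    if n_boundary_dropped:
        funnel["boundary_dropped"] = n_boundary_dropped

    # stage 4: genomic-deletion screens
    kept, removed = apply_artifact_screens(candidates)
    funnel["post_artifact_screen"] = len(kept)

    # stage 5: pooled read-support cutoff vs unannotated long introns
    profiles = conservation.build_support_profiles(
        aggregated, annotation, short_keys=[r.key for r in kept],
        min_len=cfg.min_length, max_len=cfg.max_length,
    )
    if cfg.read_cutoff is not None:
        read_cutoff, cutoff_table = cfg.read_cutoff, []
    else:
        try:
            read_cutoff, cutoff_table = conservation.select_read_cutoff(
                profiles["short"], profiles["long_unannotated"],
                n_max=cfg.read_cutoff_max,
            )
        except (NoQualifyingCutoff, ValueError) as exc:
            logger.warning("read-cutoff selection failed (%s); using 1", exc)
            read_cutoff, cutoff_table = 1, getattr(exc, "table", [])
    final = [r for r in kept if r.total_unique_reads >= read_cutoff]
    funnel["final_pool"] = len(final)

    # stage 6: classification
    classify_records(final, annotation)

    # stage 7: splicing efficiency and the support correlation
    eff_table = None
    support_corr = None
    if coverage is not None:
        eff_table = efficiency.compute_efficiencies(final, coverage)
        scored = [r for r in final if r.avg_efficiency is not None]
        if len(scored) >= 40:
            support_corr = efficiency.bin_and_correlate(
                [r.total_unique_reads for r in scored],
                [r.avg_efficiency for r in scored],
            )

    # stage 8: folding and the structure correlation
    folding.fold_intron_pool(final, engine=cfg.folding_engine)
    deltag_corr = None
    folded = [
        r for r in final
        if r.delta_g is not None and r.avg_efficiency is not None
    ]
    if len(folded) >= 40:
        deltag_corr = efficiency.bin_and_correlate(
            [r.delta_g for r in folded],
            [r.avg_efficiency for r in folded],
        )

    # stage 9: IRE1 consensus scan
    hits, searched = motifs.scan_pool(final, flank=cfg.flank)
    if searched:
        expected, pvalue = motifs.enrichment_test(len(hits), searched)
    else:
        expected, pvalue = 0.0, 1.0
    hist, near = motifs.boundary_distance_histogram(hits)

    return PipelineResult(
        config=cfg, npidr_curves=curves, sample_cutoffs=cutoffs, funnel=funnel,
        records=final, removed_records=removed, read_cutoff=read_cutoff,
        cutoff_table=cutoff_table, profiles=profiles,
        efficiency_table=eff_table, support_correlation=support_corr,
        deltag_correlation=deltag_corr, motif_hits=hits,
        motif_searched=searched, motif_expected=expected, motif_pvalue=pvalue,
        motif_boundary_hist=hist, motif_near_boundary=near,
    )


def _junction_view(rec: IntronRecord):
    """Adapter giving an IntronRecord the junction coordinate interface."""
    from .junctions import SpliceJunction

    return SpliceJunction(rec.chrom, rec.start, rec.end, rec.strand)


def write_reports(result: PipelineResult, outdir) -> None:
    """Write the TSV/BED/JSON reports for a finished run (deterministic)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(result.summary(), fh, indent=1, sort_keys=True)

    rows = []
    for s in sorted(result.npidr_curves):
        curve = result.npidr_curves[s]
        for n in sorted(curve.values):
            rows.append((s, n, f"{curve.values[n]:.6f}", curve.chosen_cutoff))
    pd.DataFrame(rows, columns=["sample_id", "cutoff", "npidr", "chosen"]).to_csv(
        outdir / "npidr.tsv", sep="\t", index=False
    )

    pd.DataFrame(
        result.cutoff_table, columns=["cutoff", "n_short", "mean_samples"]
    ).to_csv(outdir / "read_cutoff.tsv", sep="\t", index=False)

    recs = sorted(result.records, key=lambda r: r.key)
    pd.DataFrame(
        [
            (r.intron_id, r.length, r.strand, r.end_class, r.canonical,
             r.samples_detected, r.total_unique_reads, r.splice_status,
             "" if r.as_distance is None else r.as_distance, r.region,
             "" if r.frameshift is None else r.frameshift,
             "" if r.avg_efficiency is None else f"{r.avg_efficiency:.3f}",
             "" if r.max_efficiency is None else f"{r.max_efficiency:.3f}",
             "" if r.delta_g is None else f"{r.delta_g:.2f}")
            for r in recs
        ],
        columns=["intron_id", "length", "strand", "end_class", "canonical",
                 "samples_detected", "total_unique_reads", "splice_status",
                 "as_distance", "region", "frameshift", "avg_efficiency",
                 "max_efficiency", "delta_g"],
    ).to_csv(outdir / "introns.tsv", sep="\t", index=False)

    removed = sorted(result.removed_records, key=lambda r: r.key)
    pd.DataFrame(
        [
            (r.intron_id, r.length, r.artifact.direct_repeat,
             r.artifact.inverted_repeat, r.artifact.simple_repeat)
            for r in removed
        ],
        columns=["intron_id", "length", "direct_repeat", "inverted_repeat",
                 "simple_repeat"],
    ).to_csv(outdir / "artifacts.tsv", sep="\t", index=False)

    if result.efficiency_table is not None:
        result.efficiency_table.round(4).to_csv(
            outdir / "efficiency.tsv", sep="\t", index=False
        )

    pd.DataFrame(
        [(h.intron_id, h.motif, h.position, h.min_boundary_distance)
         for h in sorted(result.motif_hits,
                         key=lambda h: (h.intron_id, h.position))],
        columns=["intron_id", "motif", "position", "min_boundary_distance"],
    ).to_csv(outdir / "ire1_hits.tsv", sep="\t", index=False)

    with open(outdir / "final_introns.bed", "w") as fh:
        for r in recs:
            fh.write(
                f"{r.chrom}\t{r.start0}\t{r.end0}\t{r.intron_id}\t"
                f"{r.total_unique_reads}\t{r.strand}\n"
            )


def truth_scorecard(result: PipelineResult, truth) -> dict:
    """Score a pipeline run against the generator's planted ground truth."""
    true_keys = {t.key for t in truth if t.cls == "true_short_intron"}
    artifact_keys = {t.key for t in truth if t.cls == "deletion_artifact"}
    final_keys = {r.key for r in result.records}
    removed_keys = {r.key for r in result.removed_records}

    if not true_keys:
        raise ValueError("truth contains no planted short introns")
    tp = len(final_keys & true_keys)
    sensitivity = tp / len(true_keys)
    precision = tp / len(final_keys) if final_keys else math.nan

    artifact_sensitivity = (
        len(removed_keys & artifact_keys) / len(artifact_keys)
        if artifact_keys else math.nan
    )
    false_flag_rate = (
        len(removed_keys & true_keys) / len(true_keys) if true_keys else math.nan
    )

    eff_truth = {
        t.key: t.planted_efficiency
        for t in truth
        if t.cls == "true_short_intron" and t.planted_efficiency is not None
    }
    sq_errs = [
        (r.avg_efficiency - eff_truth[r.key]) ** 2
        for r in result.records
        if r.key in eff_truth and r.avg_efficiency is not None
    ]
    rmse = math.sqrt(sum(sq_errs) / len(sq_errs)) if sq_errs else math.nan

    return {
        "short_intron_sensitivity": sensitivity,
        "short_intron_precision": precision,
        "artifact_sensitivity": artifact_sensitivity,
        "artifact_false_flag_rate": false_flag_rate,
        "efficiency_rmse": rmse,
        "support_R": None if result.support_correlation is None
        else result.support_correlation[1],
        "deltag_R": None if result.deltag_correlation is None
        else result.deltag_correlation[1],
        "ire1_pvalue": result.motif_pvalue,
        "n_final": len(final_keys),
        "n_true_planted": len(true_keys),
    }
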
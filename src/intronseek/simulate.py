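"""Fully labeled synthetic datasets exercising every pipeline stage.

The generator stands in for aligned RNA-seq inputs: it emits a toy genome
(FASTA), a transcript annotation (GTF), per-replicate junction tables,
a window-coverage table, and a ground-truth ledger, all determined by one
seed.  Planted element classes:

* **true short introns** (10-70 nt) inside gene exons, repeat-free by
  rejection sampling against all three deletion screens; canonical ends,
  IRE1 hexamers at the 5' boundary, or plain non-canonical ends by
  configured probabilities; a configurable fraction carries a perfect
  GC-rich stem between the two 10-nt exonic flanks, so the splice sites sit
  at the base of a hairpin without tripping the intron-end screens.
  They recur in several datasets with per-replicate read support at or above
  the support boundary.
* **deletion artifacts**: constructed to trip exactly one designated screen
  (direct / inverted / simple repeat); like real somatic deletions they are
  private to one or two cell lines but reproducible between replicates.
* **annotated long introns** (every gene's real introns, seen everywhere
  with high support) and **unannotated long introns** (novel >70 nt gaps in
  a few datasets) for the conservation comparison.
* **noise junctions**: replicate-private calls below the support boundary
  (removed by the reproducibility filter) plus reproducible single-dataset
  short junctions with pooled support <= 6 (removed by the pooled-read
  cutoff).

Per-dataset coverage counts are drawn so the efficiency estimator's
expectation equals the planted efficiency; planted efficiency rises with
pooled read support and with the planted stem, giving the two correlation
signs the analysis should recover.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import AnnotationModel, Transcript
from .artifacts import screen_all
from .efficiency import TableCoverage
from .junctions import (
    GenomeRef,
    SpliceJunction,
    reverse_complement,
    write_junction_table,
)
from .motifs import IRE1_HEXAMERS

_BASES = np.array(list("ACGT"))


class GenerationError(ValueError):
    """The configuration cannot be realized (e.g. genome capacity)."""


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic study; the defaults are the study conditions."""

    seed: int = 0
    n_datasets: int = 10           # cell lines, x2 replicates each
    n_genes: int = 40
    n_true_short: int = 150
    n_artifacts_per_class: int = 20
    n_long_unannotated: int = 40
    n_single_dataset: int = 500    # reproducible single-cell-line short junctions
    n_noise_per_replicate: int = 150
    # short-intron composition
    min_length: int = 10
    max_length: int = 70
    canonical_probability: float = 0.55
    ire1_probability: float = 0.25
    structured_probability: float = 0.40
    annotated_short_fraction: float = 0.30
    as_fraction: float = 0.20      # alternative-splice-site fraction
    lncrna_gene_fraction: float = 0.15
    # read support model
    support_boundary: int = 4      # noise < boundary <= true, per replicate
    support_nb_mean: float = 12.0  # extra reads above the boundary (neg. binomial)
    support_nb_dispersion: float = 3.0
    replicate_miss_prob: float = 0.03
    sample_presence_prob: float = 0.6
    # coverage / efficiency model
    flank_depth: int = 1000
    coverage_noise: bool = True    # Poisson counts vs exact expectation
    eff_base: float = 20.0
    eff_support_slope: float = 30.0   # x pooled-support quantile
    eff_structure_bonus: float = 25.0
    eff_noise_sd: float = 8.0

    EXON_LEN = 400
    SLOTS_PER_EXON = 3
    SLOT_WIDTH = 110
    SPACER = 150


@dataclass
class TruthElement:
    """Ground-truth label for one planted element."""

    element_id: str
    cls: str          # true_short_intron | deletion_artifact | long_intron_annotated
    #                 # | long_intron_unannotated | noise_junction
    subtype: str      # artifact screen, or noise kind; '' otherwise
    chrom: str
    start: int        # 1-based first intron base
    end: int          # 1-based last intron base
    strand: str
    canonical: bool = False
    end_class: str = ""
    ire1_planted: bool = False
    structured: bool = False
    planted_efficiency: float | None = None
    planted_support: dict = field(default_factory=dict)  # dataset -> [r1, r2]
    samples_planted: list = field(default_factory=list)
    splice_status: str | None = None
    region: str | None = None
    frameshift: bool | None = None

    @property
    def key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.strand)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SyntheticDataset:
    config: GeneratorConfig
    genome: GenomeRef
    annotation: AnnotationModel
    junctions: dict  # dataset_id -> (rep1 list, rep2 list)
    coverage: TableCoverage
    truth: list[TruthElement]

    def truth_by_class(self, cls: str) -> list[TruthElement]:
        return [t for t in self.truth if t.cls == cls]

    def write_to(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.genome.write_fasta(outdir / "genome.fa")
        self.annotation.write_gtf(outdir / "annotation.gtf")
        for ds in sorted(self.junctions):
            for i, rep in enumerate(self.junctions[ds], start=1):
                write_junction_table(rep, outdir / f"{ds}_rep{i}.sj.tab")
        self.coverage.frame.to_csv(outdir / "coverage.tsv", sep="\t", index=False)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(
                [dataclasses.asdict(t) for t in self.truth],
                fh, indent=1, sort_keys=True,
            )

    @staticmethod
    def load_truth(path) -> list[TruthElement]:
        with open(path) as fh:
            return [TruthElement(**d) for d in json.load(fh)]


# --------------------------------------------------------------------------
# sequence construction helpers


def _rand_seq(rng, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _set_transcribed(genome: np.ndarray, s0: int, e0: int, strand: str,
                     context: str) -> None:
    """Write a transcribed-orientation flanked context into the genome array.

    ``context`` covers genomic [s0-10, e0+10); for minus-strand hosts the
    reverse complement is written so extraction reproduces ``context``.
    """
    if strand == "-":
        context = reverse_complement(context)
    genome[s0 - 10 : e0 + 10] = list(context)


_CANONICAL_ENDS = (("GT", "AG"), ("GC", "AG"), ("AT", "AC"))
_CANONICAL_WEIGHTS = (0.80, 0.15, 0.05)


def _make_true_short(rng, cfg: GeneratorConfig):
    """(flank5, intron, flank3, end_class, ire1, structured), repeat-free."""
    for _ in range(200):
        length = int(rng.integers(cfg.min_length, cfg.max_length + 1))
        u = rng.random()
        if u < cfg.canonical_probability:
            head, tail = _CANONICAL_ENDS[
                rng.choice(len(_CANONICAL_ENDS), p=_CANONICAL_WEIGHTS)
            ]
            intron = head + _rand_seq(rng, length - 4) + tail
            end_class = f"{head}-{tail}"
            ire1 = False
        elif u < cfg.canonical_probability + cfg.ire1_probability:
            hexamer = IRE1_HEXAMERS[rng.integers(0, len(IRE1_HEXAMERS))]
            intron = (hexamer + _rand_seq(rng, length - 6))[:length]
            end_class, ire1 = "non-canonical", True
        else:
            intron = _rand_seq(rng, length)
            end_class, ire1 = "non-canonical", False
            if any(intron[:2] == h and intron[-2:] == t for h, t in _CANONICAL_ENDS):
                continue
        structured = bool(rng.random() < cfg.structured_probability)
        if structured:
            # G/C-rich 8-bp stem between the flanks: splice sites sit at the
            # stem base without tripping the intron-end screens
            stem = "".join(
                ("G" if rng.random() < 0.5 else "C") if rng.random() < 0.85
                else ("A" if rng.random() < 0.5 else "T")
                for _ in range(8)
            )
            flank5 = _rand_seq(rng, 2) + stem
            flank3 = reverse_complement(stem) + _rand_seq(rng, 2)
        else:
            flank5, flank3 = _rand_seq(rng, 10), _rand_seq(rng, 10)
        if ire1 and end_class != "non-canonical":
            continue
        if not screen_all(flank5, intron, flank3).any:
            return flank5, intron, flank3, end_class, ire1, structured
    raise GenerationError("could not sample a repeat-free short intron")


def _make_plain_short(rng, cfg: GeneratorConfig):
    """A repeat-free short intron context with no planted features."""
    for _ in range(200):
        length = int(rng.integers(cfg.min_length, cfg.max_length + 1))
        intron = _rand_seq(rng, length)
        flank5, flank3 = _rand_seq(rng, 10), _rand_seq(rng, 10)
        if not screen_all(flank5, intron, flank3).any:
            return flank5, intron, flank3
    raise GenerationError("could not sample a repeat-free junction context")


def _make_artifact(rng, cfg: GeneratorConfig, kind: str):
    """A context tripping exactly the designated screen."""
    for _ in range(500):
        length = int(rng.integers(max(cfg.min_length, 12), cfg.max_length + 1))
        flank5, flank3 = _rand_seq(rng, 10), _rand_seq(rng, 10)
        if kind == "direct":
            if rng.random() < 0.5:
                intron = _rand_seq(rng, length - 6) + flank5[-6:]
            else:
                intron = flank3[:6] + _rand_seq(rng, length - 6)
        elif kind == "inverted":
            head = _rand_seq(rng, 6)
            intron = head + _rand_seq(rng, length - 12) + reverse_complement(head)
        elif kind == "simple":
            k = int(rng.integers(1, 6))
            unit = _rand_seq(rng, k)
            n_copies = math.ceil(0.85 * length / k)
            rep = unit * n_copies
            intron = (rep + _rand_seq(rng, length))[:length]
        else:
            raise ValueError(kind)
        flags = screen_all(flank5, intron, flank3)
        hit = {
            "direct": flags.direct_repeat,
            "inverted": flags.inverted_repeat,
            "simple": flags.simple_repeat,
        }
        if hit[kind] and sum(hit.values()) == 1:
            return flank5, intron, flank3
    raise GenerationError(f"could not construct a {kind}-repeat artifact")


# --------------------------------------------------------------------------


def _nb_reads(rng, cfg: GeneratorConfig, mean: float | None = None) -> int:
    """boundary + negative-binomial extra reads."""
    mean = cfg.support_nb_mean if mean is None else mean
    r = cfg.support_nb_dispersion
    p = r / (r + mean)
    return cfg.support_boundary + int(rng.negative_binomial(r, p))


def generate_dataset(config: GeneratorConfig | None = None,
                     seed: int | None = None) -> SyntheticDataset:
    """Generate the full labeled dataset for one configuration."""
    cfg = config or GeneratorConfig()
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    chrom = "chrS"
    datasets = [f"cell{i + 1:02d}" for i in range(cfg.n_datasets)]

    n_slots = cfg.n_genes * 3 * cfg.SLOTS_PER_EXON
    n_needed = cfg.n_true_short + 3 * cfg.n_artifacts_per_class + cfg.n_long_unannotated
    if n_needed > n_slots:
        raise GenerationError(
            f"{n_needed} planted elements exceed {n_slots} exon slots; "
            "increase n_genes"
        )

    # --- gene layout -------------------------------------------------------
    genes = []
    pos = cfg.SPACER
    for g in range(cfg.n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = "lncRNA" if rng.random() < cfg.lncrna_gene_fraction else "coding"
        intron_lens = rng.integers(100, 251, size=2)
        exons = []
        p = pos
        for i in range(3):
            exons.append((p, p + cfg.EXON_LEN))
            p += cfg.EXON_LEN
            if i < 2:
                p += int(intron_lens[i])
        cds = None
        if biotype == "coding":
            cds = (exons[0][0] + 200, exons[2][0] + 200)
        genes.append(
            {"gene_id": f"g{g + 1:03d}", "strand": strand, "biotype": biotype,
             "exons": exons, "cds": cds}
        )
        pos = p + cfg.SPACER

    junk_start = pos
    junk_width = 100
    genome_len = junk_start + cfg.n_single_dataset * junk_width + 500
    genome_arr = _BASES[rng.integers(0, 4, genome_len)].copy()

    # exon slots host engineered elements; shuffled once for random assignment
    slots = []
    for gene in genes:
        for exon_idx, (xs, xe) in enumerate(gene["exons"]):
            for s in range(cfg.SLOTS_PER_EXON):
                slots.append((gene, exon_idx, xs + 30 + s * cfg.SLOT_WIDTH))
    slots = [slots[i] for i in rng.permutation(len(slots))]
    slot_iter = iter(slots)

    truth: list[TruthElement] = []
    transcripts: list[Transcript] = []
    alt_transcripts: list[Transcript] = []
    for gene in genes:
        transcripts.append(
            Transcript(
                tx_id=gene["gene_id"] + ".t1", gene_id=gene["gene_id"],
                chrom=chrom, strand=gene["strand"], exons=list(gene["exons"]),
                cds=gene["cds"], biotype=gene["biotype"],
            )
        )

    def region_of(gene, s0, e0) -> str:
        if gene["biotype"] == "lncRNA":
            return "lncRNA"
        cs, ce = gene["cds"]
        if s0 < ce and e0 > cs:
            return "ORF"
        upstream = e0 <= cs
        if gene["strand"] == "+":
            return "5'UTR" if upstream else "3'UTR"
        return "3'UTR" if upstream else "5'UTR"

    # --- true short introns ------------------------------------------------
    n_alt = 0
    for idx in range(cfg.n_true_short):
        gene, exon_idx, slot = next(slot_iter)
        flank5, intron, flank3, end_class, ire1, structured = _make_true_short(rng, cfg)
        s0 = slot + 20
        e0 = s0 + len(intron)
        _set_transcribed(genome_arr, s0, e0, gene["strand"], flank5 + intron + flank3)

        # annotation status: annotated / AS / nested
        u = rng.random()
        xs, xe = gene["exons"][exon_idx]
        exons = list(gene["exons"])
        status = "nested"
        if u < cfg.annotated_short_fraction:
            status = "annotated"
            exons[exon_idx : exon_idx + 1] = [(xs, s0), (e0, xe)]
        elif u < cfg.annotated_short_fraction + cfg.as_fraction:
            delta = int(rng.integers(5, 31))
            as5 = rng.random() < 0.2  # most alternative sites are 3'
            plus = gene["strand"] == "+"
            if as5 == plus:  # shift the genomic-left end
                alt = (s0 - delta, e0)
                status = "AS-5'" if as5 else "AS-3'"
            else:
                alt = (s0, e0 + delta)
                status = "AS-5'" if as5 else "AS-3'"
            if xs < alt[0] and alt[1] < xe:
                exons[exon_idx : exon_idx + 1] = [(xs, alt[0]), (alt[1], xe)]
            else:
                status = "nested"
        if status != "nested":
            n_alt += 1
            alt_transcripts.append(
                Transcript(
                    tx_id=f"{gene['gene_id']}.alt{n_alt}", gene_id=gene["gene_id"],
                    chrom=chrom, strand=gene["strand"], exons=exons,
                    cds=gene["cds"], biotype=gene["biotype"],
                )
            )

        samples = [ds for ds in datasets if rng.random() < cfg.sample_presence_prob]
        while len(samples) < 2:
            extra = datasets[rng.integers(0, len(datasets))]
            if extra not in samples:
                samples.append(extra)
        samples.sort()
        support = {}
        for ds in samples:
            r1, r2 = _nb_reads(rng, cfg), _nb_reads(rng, cfg)
            if rng.random() < cfg.replicate_miss_prob:
                if rng.random() < 0.5:
                    r1 = 0
                else:
                    r2 = 0
            support[ds] = [int(r1), int(r2)]

        region = region_of(gene, s0, e0)
        length = e0 - s0
        truth.append(
            TruthElement(
                element_id=f"short{idx + 1:04d}", cls="true_short_intron",
                subtype="", chrom=chrom, start=s0 + 1, end=e0,
                strand=gene["strand"], canonical=end_class != "non-canonical",
                end_class=end_class, ire1_planted=ire1, structured=structured,
                planted_support=support, samples_planted=samples,
                splice_status=status, region=region,
                frameshift=(length % 3 != 0) if region == "ORF" else None,
            )
        )

    # planted efficiency: rises with pooled support quantile and the stem
    true_short = [t for t in truth if t.cls == "true_short_intron"]
    pooled = np.array(
        [sum(sum(v) for v in t.planted_support.values()) for t in true_short]
    )
    ranks = pooled.argsort().argsort()
    q = ranks / max(1, len(ranks) - 1)
    for t, qi in zip(true_short, q):
        e = (
            cfg.eff_base
            + cfg.eff_support_slope * qi
            + cfg.eff_structure_bonus * t.structured
            + rng.normal(0.0, cfg.eff_noise_sd)
        )
        t.planted_efficiency = float(np.clip(e, 0.0, 100.0))

    # --- deletion artifacts ------------------------------------------------
    for kind in ("direct", "inverted", "simple"):
        for a in range(cfg.n_artifacts_per_class):
            gene, exon_idx, slot = next(slot_iter)
            flank5, intron, flank3 = _make_artifact(rng, cfg, kind)
            s0 = slot + 20
            e0 = s0 + len(intron)
            _set_transcribed(
                genome_arr, s0, e0, gene["strand"], flank5 + intron + flank3
            )
            n_cells = int(rng.integers(1, 3))
            samples = sorted(
                datasets[i] for i in rng.choice(len(datasets), n_cells, replace=False)
            )
            support = {
                ds: [_nb_reads(rng, cfg, mean=8.0), _nb_reads(rng, cfg, mean=8.0)]
                for ds in samples
            }
            truth.append(
                TruthElement(
                    element_id=f"art_{kind}{a + 1:03d}", cls="deletion_artifact",
                    subtype=kind, chrom=chrom, start=s0 + 1, end=e0,
                    strand=gene["strand"], planted_support=support,
                    samples_planted=samples,
                )
            )

    # --- long introns ------------------------------------------------------
    for gi, gene in enumerate(genes):
        tx = transcripts[gi]
        for ii, (is0, ie0) in enumerate(tx.introns()):
            support = {
                ds: [_nb_reads(rng, cfg, mean=30.0), _nb_reads(rng, cfg, mean=30.0)]
                for ds in datasets
            }
            truth.append(
                TruthElement(
                    element_id=f"{gene['gene_id']}.i{ii + 1}",
                    cls="long_intron_annotated", subtype="", chrom=chrom,
                    start=is0 + 1, end=ie0, strand=gene["strand"],
                    planted_support=support, samples_planted=list(datasets),
                )
            )
    for li in range(cfg.n_long_unannotated):
        gene, exon_idx, slot = next(slot_iter)
        length = int(rng.integers(71, 86))
        s0 = slot + 10
        e0 = s0 + length
        n_cells = int(rng.integers(1, 5))
        samples = sorted(
            datasets[i] for i in rng.choice(len(datasets), n_cells, replace=False)
        )
        support = {
            ds: [_nb_reads(rng, cfg, mean=6.0), _nb_reads(rng, cfg, mean=6.0)]
            for ds in samples
        }
        truth.append(
            TruthElement(
                element_id=f"longu{li + 1:03d}", cls="long_intron_unannotated",
                subtype="", chrom=chrom, start=s0 + 1, end=e0,
                strand=gene["strand"], planted_support=support,
                samples_planted=samples,
            )
        )

    # --- single-dataset reproducible short junctions ------------------------
    for si in range(cfg.n_single_dataset):
        base = junk_start + si * junk_width + 15
        flank5, intron, flank3 = _make_plain_short(rng, cfg)
        strand = "+" if rng.random() < 0.5 else "-"
        s0 = base
        e0 = s0 + len(intron)
        _set_transcribed(genome_arr, s0, e0, strand, flank5 + intron + flank3)
        ds = datasets[int(rng.integers(0, len(datasets)))]
        pooled_target = int(rng.integers(5, 7))  # pooled support 5 or 6
        if pooled_target == 5:
            a, b = cfg.support_boundary, pooled_target - cfg.support_boundary
        else:
            a = cfg.support_boundary + int(rng.integers(0, 2))
            b = pooled_target - a
        if b < 1:
            a, b = cfg.support_boundary, pooled_target - cfg.support_boundary
        pair = [a, b] if rng.random() < 0.5 else [b, a]
        truth.append(
            TruthElement(
                element_id=f"single{si + 1:04d}", cls="noise_junction",
                subtype="single_dataset", chrom=chrom, start=s0 + 1, end=e0,
                strand=strand, planted_support={ds: pair},
                samples_planted=[ds],
                planted_efficiency=float(rng.uniform(0, 40)),
            )
        )

    # --- replicate-private noise -------------------------------------------
    noise_margin = 300
    for ds in datasets:
        for rep in (1, 2):
            for ni in range(cfg.n_noise_per_replicate):
                s0 = int(rng.integers(noise_margin, junk_start - noise_margin))
                length = int(rng.integers(cfg.min_length, 251))
                strand = ["+", "-", "."][int(rng.integers(0, 3))]
                reads = int(rng.integers(1, cfg.support_boundary))
                truth.append(
                    TruthElement(
                        element_id=f"noise_{ds}_r{rep}_{ni + 1:04d}",
                        cls="noise_junction", subtype="replicate_private",
                        chrom=chrom, start=s0 + 1, end=s0 + length,
                        strand=strand,
                        planted_support={ds: [reads, 0] if rep == 1 else [0, reads]},
                        samples_planted=[ds],
                    )
                )

    # --- emit junction tables ----------------------------------------------
    junctions: dict[str, tuple[list, list]] = {ds: ([], []) for ds in datasets}
    for t in truth:
        for ds, (r1, r2) in sorted(t.planted_support.items()):
            for rep_idx, reads in enumerate((r1, r2)):
                if reads <= 0:
                    continue
                junctions[ds][rep_idx].append(
                    SpliceJunction(
                        chrom=t.chrom, start=t.start, end=t.end, strand=t.strand,
                        motif_code=0, annotated_flag=t.cls == "long_intron_annotated",
                        unique_reads=int(reads),
                        multi_reads=int(rng.integers(0, 3)),
                        max_overhang=20, sample_id=f"{ds}_rep{rep_idx + 1}",
                    )
                )
    for ds in datasets:
        for rep in junctions[ds]:
            rep.sort(key=lambda j: (j.start, j.end, j.strand))

    # --- coverage table -----------------------------------------------------
    cov_rows = []
    for t in truth:
        if t.planted_efficiency is None:
            continue
        e = t.planted_efficiency
        iid = f"{t.chrom}:{t.start}-{t.end}:{t.strand}"
        mid_mean = cfg.flank_depth * (100.0 - e) / 100.0
        for ds in datasets:
            if cfg.coverage_noise:
                r5 = int(rng.poisson(cfg.flank_depth))
                r3 = int(rng.poisson(cfg.flank_depth))
                rm = int(rng.poisson(mid_mean))
            else:
                r5 = r3 = cfg.flank_depth
                rm = round(mid_mean)
            cov_rows.append((iid, ds, r5, rm, r3))
    coverage = TableCoverage(
        pd.DataFrame(cov_rows, columns=TableCoverage.COLUMNS)
    )

    genome = GenomeRef({chrom: "".join(genome_arr.tolist())})
    annotation = AnnotationModel(transcripts + alt_transcripts)
    return SyntheticDataset(
        config=cfg, genome=genome, annotation=annotation,
        junctions={ds: tuple(junctions[ds]) for ds in datasets},
        coverage=coverage, truth=truth,
    )


def emit_sam_coverage(dataset: SyntheticDataset, sample_id: str, path,
                      depth_scale: float = 0.05) -> None:
    """Optional aligned-read emission for the overlap-counting path.

    Writes a plain-text SAM whose reads reproduce the window-count table for
    one sample (scaled by ``depth_scale`` to keep files small): each window
    receives ``round(count * depth_scale)`` 10M reads exactly covering it.
    """
    from .efficiency import efficiency_windows

    frame = dataset.coverage.frame
    rows = frame[frame["sample_id"] == sample_id]
    chrom = dataset.genome.chroms()[0]
    clen = dataset.genome.chrom_length(chrom)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{chrom}\tLN:{clen}\n")
        rid = 0
        for row in rows.itertuples(index=False):
            c, s_e, strand = row.intron_id.split(":")
            start, end = (int(x) for x in s_e.split("-"))
            w = efficiency_windows(c, start, end, clen)
            for (ws, we), count in zip(
                (w.flank5, w.mid, w.flank3),
                (row.reads_5flank, row.reads_mid, row.reads_3flank),
            ):
                n = round(count * depth_scale)
                seq = dataset.genome.fetch(c, ws, we)
                for _ in range(n):
                    rid += 1
                    fh.write(
                        f"r{rid}\t0\t{c}\t{ws + 1}\t255\t{we - ws}M\t*\t0\t0\t"
                        f"{seq}\t*\n"
                    )
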
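"""End-to-end orchestration of the three filtering stages.

Given a reference annotation on species 1, both genomes and reciprocal chain
files, the pipeline produces three nested annotation pairs:

1. **WGA** — reciprocal chain lifting (exact round-trip required);
2. **WGA+LA** — local-alignment conservation / paralog filtering;
3. **XSAnno** — removal of exons and genes with significant
   mappability differences under an equal-expression read simulation, plus
   the truncation filter.

Every stage writes its own annotation pair, so the intermediate models are
usable (and comparable) on their own.
"""

from __future__ import annotations

import logging
import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import liftover, localalign, mapping, simulate, stats
from .formats import ChainAlignmentSet, write_gtf
from .model import AnnotationSet, SequenceStore

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    min_match: float = liftover.MIN_MATCH_CLOSE
    auto_min_match: bool = False
    min_match_grid: Tuple[float, ...] = (0.90, 0.913, 0.95, 0.98, 1.0)
    thresholds: localalign.PidPlThresholds = field(
        default_factory=localalign.PidPlThresholds
    )
    auto_thresholds: bool = False
    read_length: int = 100
    coverage: float = 10.0
    n_lanes: int = 10
    error_rate: float = 0.002
    max_mismatches: int = 2
    fdr: float = 0.01
    truncation_min_fraction: float = 1.0 / 3.0
    truncation_min_length: int = 1000
    truncation_rule: str = "and"
    seed: int = 0


@dataclass
class StageReport:
    stage: str
    genes_in: int
    genes_out: int
    transcripts_in: int
    transcripts_out: int
    exons_in: int
    exons_out: int
    reasons: Dict[str, int] = field(default_factory=dict)

    def check_monotone(self) -> None:
        assert self.genes_out <= self.genes_in
        assert self.transcripts_out <= self.transcripts_in
        assert self.exons_out <= self.exons_in


@dataclass
class PipelineResult:
    wga: Tuple[AnnotationSet, AnnotationSet]  # (Sp1-filtered, Sp2)
    wga_la: Tuple[AnnotationSet, AnnotationSet]
    xsanno: Tuple[AnnotationSet, AnnotationSet]
    reports: List[StageReport]
    dim_reports: Dict[str, pd.DataFrame]
    truncation_report: pd.DataFrame
    exon_counts: Optional[mapping.CountMatrix] = None
    gene_counts: Optional[mapping.CountMatrix] = None

    def removed_genes(self, original: AnnotationSet) -> set:
        final = set(self.xsanno[0].gene_ids())
        return set(original.gene_ids()) - final

    def removed_exons(self, original: AnnotationSet) -> set:
        final = set(self.xsanno[0].exon_map())
        return set(original.exon_map()) - final

    def biotype_summary(self, original: AnnotationSet) -> pd.DataFrame:
        """Gene counts per biotype at each stage (input, WGA, WGA+LA, final)."""
        stages = {
            "input": original,
            "WGA": self.wga[0],
            "WGA+LA": self.wga_la[0],
            "XSAnno": self.xsanno[0],
        }
        rows = {}
        for name, ann in stages.items():
            c = Counter(g.biotype for g in ann.genes)
            for bt, n in c.items():
                rows.setdefault(bt, {})[name] = n
        return pd.DataFrame(rows).T.fillna(0).astype(int)


def _report(stage: str, ann_in: AnnotationSet, ann_out: AnnotationSet, reasons) -> StageReport:
    gi, ti, ei = ann_in.counts()
    go, to, eo = ann_out.counts()
    hist: Dict[str, int] = {}
    for r in reasons:
        hist[r] = hist.get(r, 0) + 1
    rep = StageReport(stage, gi, go, ti, to, ei, eo, hist)
    rep.check_monotone()
    log.info(
        "%s: genes %d->%d, transcripts %d->%d, exons %d->%d (%s)",
        stage, gi, go, ti, to, ei, eo, hist,
    )
    return rep


def simulate_and_count(
    ann_sp1: AnnotationSet,
    ann_sp2: AnnotationSet,
    genome_sp1: SequenceStore,
    genome_sp2: SequenceStore,
    count_on: Tuple[AnnotationSet, AnnotationSet],
    cfg: PipelineConfig,
    expression_per_lane: Optional[Dict[str, List[Dict[str, float]]]] = None,
) -> Tuple[mapping.CountMatrix, mapping.CountMatrix, Dict[str, Counter], Dict[str, Counter]]:
    """Equal-expression simulation of both species, mapping to own genome,
    counting on the (possibly more filtered) annotations in ``count_on``.

    Returns (exon CountMatrix, gene CountMatrix, per-sample gene truth
    counts, per-sample discard counters).  Sample ids are sp1_L* / sp2_L*.
    """
    count_sp1, count_sp2 = count_on
    shared_keys = sorted(set(count_sp1.exon_map()) & set(count_sp2.exon_map()))
    gene_ids = sorted({k[0] for k in shared_keys})

    exon_counts_per_sample: Dict[str, Counter] = {}
    gene_counts_per_sample: Dict[str, Counter] = {}
    truth_counts: Dict[str, Counter] = {}
    discards: Dict[str, Counter] = {}

    for species, ann_src, genome, ann_count, seed_off in (
        ("sp1", ann_sp1, genome_sp1, count_sp1, 0),
        ("sp2", ann_sp2, genome_sp2, count_sp2, 1),
    ):
        transcripts = simulate.transcript_sequences(ann_src, genome)
        tx_gene = {
            t.transcript_id: g.gene_id for g in ann_src.genes for t in g.transcripts
        }
        index = mapping.MappingIndex(genome, ann_src, read_length=cfg.read_length)
        sim_cfg_sp = simulate.SimConfig(
            read_length=cfg.read_length,
            coverage=cfg.coverage,
            n_lanes=cfg.n_lanes,
            error_rate=cfg.error_rate,
            seed=(cfg.seed * 2 + seed_off) & 0x7FFFFFFF,
        )
        for lane in range(cfg.n_lanes):
            expr = None
            if expression_per_lane is not None:
                expr = expression_per_lane[species][lane]
            reads = simulate.simulate_lane(transcripts, sim_cfg_sp, lane, expr)
            sample = f"{species}_L{lane}"
            truth_counts[sample] = Counter(
                tx_gene[r.transcript_id] for r in reads
            )
            alignments, disc = mapping.map_reads(reads, index, cfg.max_mismatches)
            discards[sample] = disc
            ec, gc = mapping.count_features(alignments, ann_count)
            exon_counts_per_sample[sample] = ec
            gene_counts_per_sample[sample] = gc

    exon_lengths = {k: iv.length for k, iv in count_sp1.exon_map().items()}
    gene_lengths = count_sp1.exonic_lengths()
    exon_cm = mapping.build_count_matrix(exon_counts_per_sample, shared_keys, exon_lengths)
    gene_cm = mapping.build_count_matrix(gene_counts_per_sample, gene_ids, gene_lengths)
    return exon_cm, gene_cm, truth_counts, discards


def run_pipeline(
    ann: AnnotationSet,
    genome_sp1: SequenceStore,
    genome_sp2: SequenceStore,
    chain_fwd: ChainAlignmentSet,
    chain_back: ChainAlignmentSet,
    cfg: PipelineConfig = PipelineConfig(),
    out_dir: Optional[str] = None,
) -> PipelineResult:
    """Run the three-stage ortholog-annotation pipeline; deterministic per seed."""
    reports: List[StageReport] = []

    # ---- stage 1: reciprocal chain lifting -------------------------------
    min_match = cfg.min_match
    if cfg.auto_min_match:
        min_match = liftover.select_min_match(
            ann, chain_fwd, chain_back, cfg.min_match_grid, seed=cfg.seed
        )
        log.info("selected min_match=%s", min_match)
    ann2_wga, ann1_wga, rec_report = liftover.reciprocal_convert(
        ann, chain_fwd, chain_back, min_match
    )
    reports.append(
        _report("WGA", ann, ann1_wga,
                [s for s in rec_report.exon_status.values() if s != "kept"])
    )

    # ---- stage 2: local-alignment filter ---------------------------------
    evidence = localalign.collect_evidence(ann1_wga, ann2_wga, genome_sp1, genome_sp2)
    thr = cfg.thresholds
    if cfg.auto_thresholds:
        thr = localalign.choose_thresholds(evidence)
        log.info("selected thresholds %s", thr)
    ann1_la, ann2_la, la_reasons = localalign.la_filter(
        ann1_wga, ann2_wga, genome_sp1, genome_sp2, thr, evidence=evidence
    )
    reports.append(
        _report("WGA+LA", ann1_wga, ann1_la,
                [r for r in la_reasons.values() if r != "kept"])
    )

    # ---- stage 3: mappability-difference + truncation filters ------------
    # reads come from the stage-1 annotation; counting uses stage-2 survivors
    exon_cm, gene_cm, _truth, discards = simulate_and_count(
        ann1_wga, ann2_wga, genome_sp1, genome_sp2, (ann1_la, ann2_la), cfg
    )
    samples_sp1 = [s for s in exon_cm.sample_ids if s.startswith("sp1")]
    samples_sp2 = [s for s in exon_cm.sample_ids if s.startswith("sp2")]
    ann1_dim, dim_reports = stats.dim_filter(
        ann1_la, exon_cm, gene_cm, samples_sp1, samples_sp2, alpha=cfg.fdr
    )
    ann1_xs, trunc_report = stats.truncation_filter(
        ann1_dim,
        ann.exonic_lengths(),
        min_fraction=cfg.truncation_min_fraction,
        min_length=cfg.truncation_min_length,
        rule=cfg.truncation_rule,
    )
    keep_keys = set(ann1_xs.exon_map())
    ann2_xs = ann2_la.subset_exons(keep_keys)
    n_dim_exons = int(dim_reports["exons"]["removed"].sum())
    n_dim_genes = int(dim_reports["genes"]["removed"].sum())
    n_trunc = int(trunc_report["removed"].sum())
    reports.append(
        _report("XSAnno", ann1_la, ann1_xs,
                ["dim_exon"] * n_dim_exons + ["dim_gene"] * n_dim_genes
                + ["truncated"] * n_trunc)
    )

    result = PipelineResult(
        wga=(ann1_wga, ann2_wga),
        wga_la=(ann1_la, ann2_la),
        xsanno=(ann1_xs, ann2_xs),
        reports=reports,
        dim_reports=dim_reports,
        truncation_report=trunc_report,
        exon_counts=exon_cm,
        gene_counts=gene_cm,
    )
    _assert_nesting(result)

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for name, (a1, a2) in (
            ("wga", result.wga), ("wga_la", result.wga_la), ("xsanno", result.xsanno)
        ):
            write_gtf(a1, os.path.join(out_dir, f"{name}.sp1.gtf"))
            write_gtf(a2, os.path.join(out_dir, f"{name}.sp2.gtf"))
        with open(os.path.join(out_dir, "stage_reports.tsv"), "w") as fh:
            fh.write("stage\tgenes_in\tgenes_out\ttranscripts_in\ttranscripts_out\t"
                     "exons_in\texons_out\treasons\n")
            for r in reports:
                fh.write(
                    f"{r.stage}\t{r.genes_in}\t{r.genes_out}\t{r.transcripts_in}\t"
                    f"{r.transcripts_out}\t{r.exons_in}\t{r.exons_out}\t{r.reasons}\n"
                )
    return result


def bias_assessment(
    ann: AnnotationSet,
    genome_sp1: SequenceStore,
    genome_sp2: SequenceStore,
    chain_fwd: ChainAlignmentSet,
    chain_back: ChainAlignmentSet,
    cfg: PipelineConfig = PipelineConfig(),
    expression_noise_sd: float = 0.2,
) -> pd.DataFrame:
    """Per-gene inter-species log2FC from mapped counts vs generated truth.

    Both species are simulated with the same per-gene expected expression but
    independent lane-level lognormal variability (sd on the log scale), so
    the mapping-free fold change is centred at zero with a common variance
    while the mapped fold change additionally carries any mappability loss.
    Returns a DataFrame with columns gene_id, fc_mapped, fc_truth.
    """
    ann2_wga, ann1_wga, _ = liftover.reciprocal_convert(
        ann, chain_fwd, chain_back, cfg.min_match
    )
    tx_ids = [t.transcript_id for g in ann1_wga.genes for t in g.transcripts]
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 991])
    mu = -0.5 * expression_noise_sd**2  # lognormal with mean 1
    expression_per_lane = {
        sp: [
            {t: float(rng.lognormal(mu, expression_noise_sd)) for t in tx_ids}
            for _ in range(cfg.n_lanes)
        ]
        for sp in ("sp1", "sp2")
    }
    _, gene_cm, truth_counts, _ = simulate_and_count(
        ann1_wga, ann2_wga, genome_sp1, genome_sp2,
        (ann1_wga, ann2_wga), cfg, expression_per_lane,
    )

    def mean_rpkm(cm_counts, lengths, samples, counts_by_sample=None):
        vals = []
        for s in samples:
            if counts_by_sample is None:
                j = gene_cm.sample_ids.index(s)
                col = gene_cm.counts[:, j].astype(float)
            else:
                col = np.array(
                    [counts_by_sample[s].get(g, 0) for g in gene_cm.feature_ids],
                    dtype=float,
                )
            total = col.sum()
            vals.append(col / (lengths / 1000.0) / (total / 1e6))
        return np.mean(vals, axis=0)

    lengths = gene_cm.lengths.astype(float)
    s1 = [s for s in gene_cm.sample_ids if s.startswith("sp1")]
    s2 = [s for s in gene_cm.sample_ids if s.startswith("sp2")]
    mapped_fc = stats.log2fc_rpkm(
        mean_rpkm(gene_cm.counts, lengths, s1),
        mean_rpkm(gene_cm.counts, lengths, s2),
    )
    truth_fc = stats.log2fc_rpkm(
        mean_rpkm(None, lengths, s1, truth_counts),
        mean_rpkm(None, lengths, s2, truth_counts),
    )
    return pd.DataFrame(
        {"gene_id": gene_cm.feature_ids, "fc_mapped": mapped_fc, "fc_truth": truth_fc}
    )


def _assert_nesting(result: PipelineResult) -> None:
    """Stage outputs must be nested and per-gene exonic length non-increasing."""
    g_wga = set(result.wga[0].gene_ids())
    g_la = set(result.wga_la[0].gene_ids())
    g_xs = set(result.xsanno[0].gene_ids())
    if not (g_xs <= g_la <= g_wga):
        raise AssertionError("stage gene sets are not nested")
    len_wga = result.wga[0].exonic_lengths()
    len_la = result.wga_la[0].exonic_lengths()
    len_xs = result.xsanno[0].exonic_lengths()
    for gid, L in len_la.items():
        if L > len_wga[gid]:
            raise AssertionError(f"gene {gid} grew between WGA and WGA+LA")
    for gid, L in len_xs.items():
        if L > len_la[gid]:
            raise AssertionError(f"gene {gid} grew between WGA+LA and XSAnno")
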
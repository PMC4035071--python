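"""Synthetic two-species genome pairs with known orthologs and planted hazards.

The generator builds a species-1 genome gene by gene, derives species 2 by a
recorded edit script (substitutions everywhere, indels restricted to
non-exonic sequence by default, whole-exon deletions, unannotated
high-identity paralog copies, single-exon translocations) and emits the
chain files directly from that edit script, so chain correctness is a
construction property rather than an alignment result.  Truth labels per
gene/exon make pipeline recovery measurable.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .formats import Chain, ChainAlignmentSet, write_chain, write_fasta, write_gtf
from .model import (
    AnnotationSet,
    ExonKey,
    GeneModel,
    GenomicInterval,
    SequenceStore,
    TranscriptModel,
)

_ALPH = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class FixtureConfig:
    n_genes: int = 30
    exons_per_gene: Tuple[int, int] = (2, 5)
    exon_length: Tuple[int, int] = (120, 240)
    intron_length: Tuple[int, int] = (60, 300)
    intergenic: Tuple[int, int] = (300, 800)
    divergence: float = 0.01  # per-base substitution rate Sp1 vs Sp2
    indel_rate: float = 0.0005  # per non-exonic base
    indel_length: Tuple[int, int] = (1, 10)
    n_paralog_sp1: int = 0
    n_paralog_sp2: int = 0
    n_paralog_both: int = 0
    paralog_identity: Tuple[float, float] = (0.98, 1.0)
    n_lift_fail: int = 0  # genes with one exon deleted in Sp2
    n_truncation: int = 0  # genes with most exonic length deleted in Sp2
    n_translocated: int = 0  # genes with one exon moved to another chromosome
    n_exon_gap: int = 0  # genes with a small internal Sp2 deletion in one exon
    exon_gap_length: Tuple[int, int] = (4, 12)
    n_dex: int = 0  # genes with a true expression fold change
    dex_fc: float = 4.0
    seed: int = 0

    def planted_total(self) -> int:
        return (
            self.n_paralog_sp1 + self.n_paralog_sp2 + self.n_paralog_both
            + self.n_lift_fail + self.n_truncation + self.n_translocated
            + self.n_exon_gap + self.n_dex
        )


@dataclass
class FixtureTruth:
    gene_class: Dict[str, str] = field(default_factory=dict)
    deleted_exons: Set[ExonKey] = field(default_factory=set)
    gap_exons: Set[ExonKey] = field(default_factory=set)
    translocated_exons: Set[ExonKey] = field(default_factory=set)
    exon_sp2: Dict[ExonKey, GenomicInterval] = field(default_factory=dict)
    paralog_copies: Dict[str, List[Tuple[str, GenomicInterval]]] = field(default_factory=dict)
    expression_fc: Dict[str, float] = field(default_factory=dict)

    def genes_of_class(self, cls: str) -> List[str]:
        return sorted(g for g, c in self.gene_class.items() if c == cls)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tclass\texpression_fc\n")
            for gid in sorted(self.gene_class):
                fh.write(
                    f"{gid}\t{self.gene_class[gid]}\t"
                    f"{self.expression_fc.get(gid, 1.0)}\n"
                )


@dataclass
class FixtureBundle:
    config: FixtureConfig
    genome_sp1: SequenceStore
    genome_sp2: SequenceStore
    annotation: AnnotationSet
    chain_fwd: ChainAlignmentSet  # Sp1 -> Sp2
    chain_back: ChainAlignmentSet  # Sp2 -> Sp1
    truth: FixtureTruth

    def write(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        write_fasta(self.genome_sp1, os.path.join(out_dir, "sp1.fa"))
        write_fasta(self.genome_sp2, os.path.join(out_dir, "sp2.fa"))
        write_gtf(self.annotation, os.path.join(out_dir, "sp1.gtf"))
        write_chain(self.chain_fwd, os.path.join(out_dir, "sp1ToSp2.chain"))
        write_chain(self.chain_back, os.path.join(out_dir, "sp2ToSp1.chain"))
        self.truth.to_tsv(os.path.join(out_dir, "truth.tsv"))
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump({"config": asdict(self.config)}, fh, indent=2, default=list)


# ---------------------------------------------------------------------------
# Sequence helpers
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _ALPH[rng.integers(0, 4, size=n)].tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Per-base substitution to a uniformly chosen different base."""
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    for pos in hit:
        choices = _ALPH[_ALPH != arr[pos]]
        arr[pos] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# Segment script
# ---------------------------------------------------------------------------

# Each chromosome is a list of segments:
#   ("A", sp1_seq, sp2_seq)  aligned, equal length (substitutions only)
#   ("T1", sp1_seq)          present in Sp1 only (chain target gap, dt)
#   ("T2", sp2_seq)          present in Sp2 only (chain query gap, dq)


def _noncoding_segments(
    rng: np.random.Generator, cfg: FixtureConfig, n: int
) -> List[Tuple]:
    """Aligned spacer of ~n Sp1 bases with optional non-exonic indels."""
    segs: List[Tuple] = []
    remaining = n
    while remaining > 0:
        if cfg.indel_rate > 0:
            gap = rng.geometric(cfg.indel_rate)
        else:
            gap = remaining + 1
        chunk = min(gap, remaining)
        s1 = _random_seq(rng, chunk)
        segs.append(("A", s1, _mutate(rng, s1, cfg.divergence)))
        remaining -= chunk
        if remaining > 0:  # place one indel
            ln = int(rng.integers(cfg.indel_length[0], cfg.indel_length[1] + 1))
            if rng.random() < 0.5:
                segs.append(("T1", _random_seq(rng, ln)))
                remaining -= min(ln, remaining)
            else:
                segs.append(("T2", _random_seq(rng, ln)))
    return segs


def _segments_to_sequences(segments: List[Tuple]) -> Tuple[str, str]:
    s1 = "".join(s[1] for s in segments if s[0] in ("A", "T1"))
    s2 = "".join(
        (s[2] if s[0] == "A" else s[1]) for s in segments if s[0] in ("A", "T2")
    )
    return s1, s2


def _segments_to_chain(
    segments: List[Tuple],
    t_name: str,
    q_name: str,
    t_size: int,
    q_size: int,
    chain_id: str,
    score: Optional[float] = None,
) -> Optional[Chain]:
    """Build the Sp1->Sp2 chain implied by a segment script."""
    blocks: List[Tuple[int, int, int]] = []
    t_pos = q_pos = 0
    t_start = q_start = None
    size = dt = dq = 0
    for seg in segments:
        kind = seg[0]
        n = len(seg[1])
        if kind == "A":
            if t_start is None:
                t_start, q_start = t_pos, q_pos
            if dt or dq:
                blocks.append((size, dt, dq))
                size, dt, dq = 0, 0, 0
            size += n
            t_pos += n
            q_pos += n
        elif kind == "T1":
            if t_start is not None:
                dt += n
            t_pos += n
        else:  # T2
            if t_start is not None:
                dq += n
            q_pos += n
    if t_start is None or size == 0:
        return None
    blocks.append((size, 0, 0))
    t_end = t_start + sum(b[0] + b[1] for b in blocks)
    q_end = q_start + sum(b[0] + b[2] for b in blocks)
    aligned = sum(b[0] for b in blocks)
    return Chain(
        score=float(score if score is not None else aligned),
        t_name=t_name,
        t_size=t_size,
        t_strand="+",
        t_start=t_start,
        t_end=t_end,
        q_name=q_name,
        q_size=q_size,
        q_strand="+",
        q_start=q_start,
        q_end=q_end,
        chain_id=chain_id,
        blocks=blocks,
    )


def invert_chain(c: Chain, chain_id: Optional[str] = None) -> Chain:
    """Swap target and query of a '+'/'+' chain."""
    assert c.q_strand == "+"
    return Chain(
        score=c.score,
        t_name=c.q_name,
        t_size=c.q_size,
        t_strand="+",
        t_start=c.q_start,
        t_end=c.q_end,
        q_name=c.t_name,
        q_size=c.t_size,
        q_strand="+",
        q_start=c.t_start,
        q_end=c.t_end,
        chain_id=chain_id or c.chain_id,
        blocks=[(size, dq, dt) for size, dt, dq in c.blocks],
    )


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------


def _assign_classes(cfg: FixtureConfig, rng: np.random.Generator) -> List[str]:
    if cfg.planted_total() > cfg.n_genes:
        raise ValueError("plans exceed n_genes")
    classes = (
        ["paralog_sp1"] * cfg.n_paralog_sp1
        + ["paralog_sp2"] * cfg.n_paralog_sp2
        + ["paralog_both"] * cfg.n_paralog_both
        + ["lift_fail"] * cfg.n_lift_fail
        + ["truncation_case"] * cfg.n_truncation
        + ["translocated"] * cfg.n_translocated
        + ["exon_gap"] * cfg.n_exon_gap
        + ["dex"] * cfg.n_dex
    )
    classes += ["consistent"] * (cfg.n_genes - len(classes))
    rng.shuffle(classes)
    return classes


def generate_pair(cfg: FixtureConfig) -> FixtureBundle:
    """Generate a two-species fixture bundle; deterministic per cfg.seed."""
    rng = np.random.default_rng(cfg.seed & 0x7FFFFFFF)
    classes = _assign_classes(cfg, rng)
    truth = FixtureTruth()

    segments: List[Tuple] = []  # chr1 script
    chr2_segments: List[Tuple] = []  # translocation landing chromosome (Sp2 side)
    genes: List[GeneModel] = []
    trans_chains: List[Tuple[int, int, int]] = []  # (sp1_start, len, sp2_chr2_start)

    def sp1_pos() -> int:
        return sum(len(s[1]) for s in segments if s[0] in ("A", "T1"))

    def sp2_pos() -> int:
        return sum(len(s[1]) for s in segments if s[0] in ("A", "T2"))

    def chr2_sp2_pos() -> int:
        return sum(len(s[1]) for s in chr2_segments if s[0] == "T2") + sum(
            len(s[1]) for s in chr2_segments if s[0] == "A"
        )

    # chr2 exists in both species (a small aligned anchor) so both FASTAs
    # contain it; translocated copies are appended as Sp2-only segments.
    anchor = _random_seq(rng, 500)
    chr2_segments.append(("A", anchor, _mutate(rng, anchor, cfg.divergence)))

    paralog_sequences: List[Tuple[str, str, str]] = []  # (class, gene_id, seq source)
    paralog_sources: Dict[str, str] = {}  # Sp2-side sources for sp2-only copies

    for gi, cls in enumerate(classes):
        gid = f"G{gi:04d}"
        tid = f"T{gi:04d}"
        truth.gene_class[gid] = cls
        strand = "+" if gi % 2 == 0 else "-"

        segments.extend(
            _noncoding_segments(rng, cfg, int(rng.integers(*cfg.intergenic)))
        )

        if cls == "truncation_case":
            n_exons = 5
            exon_lens = [int(rng.integers(230, 260)) for _ in range(n_exons)]
        else:
            n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
            if cls in ("lift_fail", "translocated", "exon_gap"):
                n_exons = max(n_exons, 3)
            exon_lens = [
                int(rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1))
                for _ in range(n_exons)
            ]

        if cls == "lift_fail":
            deleted = {int(rng.integers(0, n_exons))}
        elif cls == "truncation_case":
            keep_one = int(rng.integers(0, n_exons))
            deleted = set(range(n_exons)) - {keep_one}
        else:
            deleted = set()
        translocated = {int(rng.integers(0, n_exons))} if cls == "translocated" else set()
        gap_exon = int(rng.integers(0, n_exons)) if cls == "exon_gap" else None

        exon_ivs: List[GenomicInterval] = []
        exon_seqs_sp1: List[str] = []
        exon_seqs_sp2: List[str] = []
        for ei in range(n_exons):
            if ei > 0:
                segments.extend(
                    _noncoding_segments(rng, cfg, int(rng.integers(*cfg.intron_length)))
                )
            start = sp1_pos()
            e_len = exon_lens[ei]
            e_seq = _random_seq(rng, e_len)
            key: ExonKey = (gid, tid, ei)
            if ei in deleted:
                segments.append(("T1", e_seq))
                truth.deleted_exons.add(key)
            elif ei in translocated:
                segments.append(("T1", e_seq))
                truth.translocated_exons.add(key)
                moved = _mutate(rng, e_seq, cfg.divergence)
                chr2_start = chr2_sp2_pos()
                chr2_segments.append(("T2", moved))
                trans_chains.append((start, e_len, chr2_start))
                truth.exon_sp2[key] = GenomicInterval("chr2", chr2_start, chr2_start + e_len, strand)
            elif gap_exon is not None and ei == gap_exon:
                gap_len = int(rng.integers(cfg.exon_gap_length[0], cfg.exon_gap_length[1] + 1))
                cut = e_len // 2
                left, mid, right = e_seq[:cut], e_seq[cut : cut + gap_len], e_seq[cut + gap_len :]
                segments.append(("A", left, _mutate(rng, left, cfg.divergence)))
                segments.append(("T1", mid))
                segments.append(("A", right, _mutate(rng, right, cfg.divergence)))
                truth.gap_exons.add(key)
            else:
                sp2_seq = _mutate(rng, e_seq, cfg.divergence)
                segments.append(("A", e_seq, sp2_seq))
                exon_seqs_sp2.append(sp2_seq)
            exon_ivs.append(GenomicInterval("chr1", start, start + e_len, strand))
            exon_seqs_sp1.append(e_seq)

        if cls == "paralog_sp2":
            # the hazard must duplicate the *Sp2* gene sequence, so that
            # Sp2 reads genuinely multimap between gene and copy
            paralog_sources[gid] = "".join(exon_seqs_sp2)

        genes.append(GeneModel(gid, [TranscriptModel(tid, exon_ivs)]))
        if cls == "dex":
            truth.expression_fc[gid] = cfg.dex_fc
        if cls.startswith("paralog"):
            src1 = "".join(
                s for i, s in enumerate(exon_seqs_sp1) if i not in deleted
            )
            paralog_sequences.append((cls, gid, src1))

    # trailing spacer, then unannotated paralog copies in dedicated slots
    segments.extend(_noncoding_segments(rng, cfg, int(rng.integers(*cfg.intergenic))))
    for cls, gid, src in paralog_sequences:
        identity = rng.uniform(*cfg.paralog_identity)
        if cls == "paralog_sp2":
            src = paralog_sources[gid]
        copy = _mutate(rng, src, 1.0 - identity)
        start1 = sp1_pos()
        if cls == "paralog_sp1":
            segments.append(("T1", copy))
            truth.paralog_copies.setdefault(gid, []).append(
                ("sp1", GenomicInterval("chr1", start1, start1 + len(copy)))
            )
        elif cls == "paralog_sp2":
            start2 = sp2_pos()
            segments.append(("T2", copy))
            truth.paralog_copies.setdefault(gid, []).append(
                ("sp2", GenomicInterval("chr1", start2, start2 + len(copy)))
            )
        else:  # both
            segments.append(("A", copy, _mutate(rng, copy, cfg.divergence)))
            truth.paralog_copies.setdefault(gid, []).append(
                ("both", GenomicInterval("chr1", start1, start1 + len(copy)))
            )
        segments.extend(
            _noncoding_segments(rng, cfg, int(rng.integers(*cfg.intergenic)))
        )

    # realise sequences
    chr1_sp1, chr1_sp2 = _segments_to_sequences(segments)
    chr2_sp1, chr2_sp2 = _segments_to_sequences(chr2_segments)
    genome_sp1 = SequenceStore({"chr1": chr1_sp1, "chr2": chr2_sp1})
    genome_sp2 = SequenceStore({"chr1": chr1_sp2, "chr2": chr2_sp2})

    # record the expected Sp2 image of every aligned exon
    sp1_to_sp2 = _build_offset_map(segments)
    for g in genes:
        for t in g.transcripts:
            for i, e in enumerate(t.exons):
                key = (g.gene_id, t.transcript_id, i)
                if key in truth.deleted_exons or key in truth.translocated_exons:
                    continue
                lo = sp1_to_sp2.get(e.start)
                hi_base = sp1_to_sp2.get(e.end - 1)
                if key in truth.gap_exons:
                    # image spans first..last aligned base
                    lo = _first_aligned_image(sp1_to_sp2, e.start, e.end)
                    hi_base = _last_aligned_image(sp1_to_sp2, e.start, e.end)
                if lo is not None and hi_base is not None:
                    truth.exon_sp2[key] = GenomicInterval("chr1", lo, hi_base + 1, e.strand)

    # chains
    main = _segments_to_chain(
        segments, "chr1", "chr1", len(chr1_sp1), len(chr1_sp2), "1"
    )
    anchor_chain = _segments_to_chain(
        chr2_segments, "chr2", "chr2", len(chr2_sp1), len(chr2_sp2), "2"
    )
    fwd = [c for c in (main, anchor_chain) if c is not None]
    for n, (t_start, length, q_start) in enumerate(trans_chains, start=3):
        fwd.append(
            Chain(
                score=1e9,  # must outrank the main chain over its exon
                t_name="chr1",
                t_size=len(chr1_sp1),
                t_strand="+",
                t_start=t_start,
                t_end=t_start + length,
                q_name="chr2",
                q_size=len(chr2_sp2),
                q_strand="+",
                q_start=q_start,
                q_end=q_start + length,
                chain_id=str(n),
                blocks=[(length, 0, 0)],
            )
        )
    chain_fwd = ChainAlignmentSet(fwd)
    chain_back = ChainAlignmentSet([invert_chain(c) for c in fwd])

    return FixtureBundle(
        config=cfg,
        genome_sp1=genome_sp1,
        genome_sp2=genome_sp2,
        annotation=AnnotationSet(genes),
        chain_fwd=chain_fwd,
        chain_back=chain_back,
        truth=truth,
    )


def _build_offset_map(segments: List[Tuple]) -> Dict[int, int]:
    """Sp1 position -> Sp2 position for every aligned base of the script."""
    out: Dict[int, int] = {}
    p1 = p2 = 0
    for seg in segments:
        kind = seg[0]
        n = len(seg[1])
        if kind == "A":
            for i in range(n):
                out[p1 + i] = p2 + i
            p1 += n
            p2 += n
        elif kind == "T1":
            p1 += n
        else:
            p2 += n
    return out


def _first_aligned_image(m: Dict[int, int], start: int, end: int) -> Optional[int]:
    for p in range(start, end):
        if p in m:
            return m[p]
    return None


def _last_aligned_image(m: Dict[int, int], start: int, end: int) -> Optional[int]:
    for p in range(end - 1, start - 1, -1):
        if p in m:
            return m[p]
    return None


# ---------------------------------------------------------------------------
# Standalone paralog planting (for targeted tests)
# ---------------------------------------------------------------------------


def plant_paralog(
    genome: SequenceStore,
    source: str,
    identity: float,
    chrom: str,
    seed: int = 0,
) -> Tuple[SequenceStore, GenomicInterval]:
    """Append a mutated copy of ``source`` to a chromosome's end.

    The copy is a hazard, not a gene: it is returned with its coordinates but
    is never added to any annotation or chain.
    """
    if not (0.9 < identity <= 1.0):
        raise ValueError("identity must be in (0.9, 1.0]")
    rng = np.random.default_rng(seed)
    copy = _mutate(rng, source, 1.0 - identity)
    old = genome.sequences[chrom]
    new_store = SequenceStore({**genome.sequences, chrom: old + copy})
    return new_store, GenomicInterval(chrom, len(old), len(old) + len(copy))


# ---------------------------------------------------------------------------
# Truth evaluation
# ---------------------------------------------------------------------------


def truth_eval(
    removed_genes: Set[str],
    removed_exons: Set[ExonKey],
    truth: FixtureTruth,
) -> Dict[str, float]:
    """Confusion summary: per-hazard-class removal sensitivity and the
    false-removal rate among consistent genes."""
    out: Dict[str, float] = {}
    for cls in ("paralog_sp1", "paralog_sp2", "paralog_both", "truncation_case",
                "translocated"):
        planted = truth.genes_of_class(cls)
        if planted:
            out[f"sensitivity_{cls}"] = sum(
                1 for g in planted if g in removed_genes
            ) / len(planted)
    if truth.deleted_exons:
        out["sensitivity_deleted_exons"] = sum(
            1 for k in truth.deleted_exons if k in removed_exons
        ) / len(truth.deleted_exons)
    consistent = truth.genes_of_class("consistent") + truth.genes_of_class("dex")
    if consistent:
        out["false_removal_rate"] = sum(
            1 for g in consistent if g in removed_genes
        ) / len(consistent)
        out["false_removals"] = float(sum(1 for g in consistent if g in removed_genes))
    return out
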
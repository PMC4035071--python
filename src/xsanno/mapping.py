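"""Stage 3b: unique-best-match spliced read mapping and feature counting.

A read is kept only when exactly one genomic placement (genome-contiguous or
across an annotated splice junction) attains the minimal mismatch count and
that count is at most ``max_mismatches`` (default 2) — strict uniqueness, the
property the mappability-difference filter measures.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .model import AnnotationSet, ExonKey, GenomicInterval, SequenceStore


@dataclass
class ReadAlignment:
    read_id: str
    intervals: Tuple[GenomicInterval, ...]  # one interval, or two across a junction
    mismatches: int
    unique: bool = True


@dataclass
class CountMatrix:
    feature_ids: List
    sample_ids: List[str]
    counts: np.ndarray  # features x samples, nonnegative ints
    lengths: np.ndarray  # feature lengths in bases

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if (self.lengths <= 0).any():
            raise ValueError("feature lengths must be positive")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.counts,
            index=[_feature_str(f) for f in self.feature_ids],
            columns=self.sample_ids,
        )
        df.insert(0, "length", self.lengths)
        df.index.name = "feature"
        return df


def _feature_str(f) -> str:
    return "|".join(str(x) for x in f) if isinstance(f, tuple) else str(f)


class MappingIndex:
    """Exact k-mer index over a genome plus spliced junction sequences.

    Junction sequences carry ``read_length - 1`` exonic bases on each side of
    every annotated intron, so any read overhanging a junction by >= 1 base
    has a candidate placement.
    """

    def __init__(
        self,
        genome: SequenceStore,
        ann: Optional[AnnotationSet] = None,
        read_length: int = 100,
        k: Optional[int] = None,
    ):
        self.read_length = read_length
        # pigeonhole for 2 mismatches: 3 disjoint seeds of length ~L/3
        self.k = k if k is not None else max(read_length // 3, 1)
        if self.k > read_length:
            raise ValueError("seed length exceeds read length")
        self.genome_arrays: Dict[str, np.ndarray] = {
            c: np.frombuffer(s.encode(), dtype=np.uint8)
            for c, s in genome.sequences.items()
        }
        self.kmers: Dict[bytes, List[Tuple]] = {}
        for chrom, arr in self.genome_arrays.items():
            b = arr.tobytes()
            for i in range(len(b) - self.k + 1):
                self.kmers.setdefault(b[i : i + self.k], []).append(("g", chrom, i))

        # junction library
        self.junctions: List[Tuple[str, int, int, str]] = []
        self.junction_arrays: List[np.ndarray] = []
        self.junction_left_start: List[int] = []
        seen = set()
        if ann is not None:
            flank = read_length - 1
            for g in ann.genes:
                for t in g.transcripts:
                    for chrom, donor, acceptor, strand in t.junctions():
                        key = (chrom, donor, acceptor)
                        if key in seen:
                            continue
                        seen.add(key)
                        arr = self.genome_arrays[chrom]
                        left_start = max(0, donor - flank)
                        right_end = min(len(arr), acceptor + flank)
                        jseq = np.concatenate([arr[left_start:donor], arr[acceptor:right_end]])
                        j_idx = len(self.junctions)
                        self.junctions.append((chrom, donor, acceptor, strand))
                        self.junction_arrays.append(jseq)
                        self.junction_left_start.append(left_start)
                        jb = jseq.tobytes()
                        for i in range(len(jb) - self.k + 1):
                            self.kmers.setdefault(jb[i : i + self.k], []).append(
                                ("j", j_idx, i)
                            )

    def seed_offsets(self) -> List[int]:
        L, k = self.read_length, self.k
        return sorted({0, (L - k) // 2, L - k})

    def _footprint(self, kind: str, where, pos: int) -> Optional[Tuple]:
        """Genomic footprint of a full-length placement starting at pos."""
        L = self.read_length
        if kind == "g":
            arr = self.genome_arrays[where]
            if pos < 0 or pos + L > len(arr):
                return None
            return ((where, pos, pos + L),)
        j_idx = where
        jseq = self.junction_arrays[j_idx]
        if pos < 0 or pos + L > len(jseq):
            return None
        chrom, donor, acceptor, _strand = self.junctions[j_idx]
        left_len = donor - self.junction_left_start[j_idx]
        g_start = self.junction_left_start[j_idx] + pos
        if pos + L <= left_len:  # entirely left of the junction
            return ((chrom, g_start, g_start + L),)
        if pos >= left_len:  # entirely right
            start = acceptor + (pos - left_len)
            return ((chrom, start, start + L),)
        right = pos + L - left_len
        return ((chrom, g_start, donor), (chrom, acceptor, acceptor + right))

    def _mismatches(self, kind: str, where, pos: int, read: np.ndarray) -> int:
        seq = self.genome_arrays[where] if kind == "g" else self.junction_arrays[where]
        return int(np.count_nonzero(seq[pos : pos + len(read)] != read))


def map_read(
    read_seq: str, index: MappingIndex, max_mismatches: int = 2, read_id: str = ""
) -> Tuple[Optional[ReadAlignment], str]:
    """Map one read; returns (alignment, reason). reason is '' on success,
    else one of unmapped / multimapped / too_many_mismatches."""
    L = index.read_length
    if len(read_seq) != L:
        raise ValueError(f"read length {len(read_seq)} != index read length {L}")
    from .model import reverse_complement

    k = index.k
    # both orientations are searched (unstranded protocol); a footprint is
    # scored by its best mismatch count over orientations
    best: Dict[Tuple, int] = {}
    for oriented in (read_seq, reverse_complement(read_seq)):
        read = np.frombuffer(oriented.encode(), dtype=np.uint8)
        b = read.tobytes()
        candidates: Set[Tuple] = set()
        for off in index.seed_offsets():
            for kind, where, pos in index.kmers.get(b[off : off + k], ()):
                candidates.add((kind, where, pos - off))
        for kind, where, pos in candidates:
            fp = index._footprint(kind, where, pos)
            if fp is None:
                continue
            mm = index._mismatches(kind, where, pos, read)
            if fp not in best or mm < best[fp]:
                best[fp] = mm
    if not best:
        return None, "unmapped"

    min_mm = min(best.values())
    if min_mm > max_mismatches:
        return None, "too_many_mismatches"
    winners = [fp for fp, mm in best.items() if mm == min_mm]
    if len(winners) > 1:
        return None, "multimapped"
    fp = winners[0]
    ivs = tuple(GenomicInterval(c, s, e) for c, s, e in fp)
    return ReadAlignment(read_id, ivs, min_mm, unique=True), ""


def map_reads(
    reads: Iterable, index: MappingIndex, max_mismatches: int = 2
) -> Tuple[List[ReadAlignment], Counter]:
    """Map a collection of SimulatedRead (or (id, seq) pairs)."""
    alignments: List[ReadAlignment] = []
    discards: Counter = Counter()
    for r in reads:
        rid, seq = (r.read_id, r.sequence) if hasattr(r, "read_id") else r
        aln, reason = map_read(seq, index, max_mismatches, read_id=rid)
        if aln is None:
            discards[reason] += 1
        else:
            alignments.append(aln)
    return alignments, discards


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------


def _exon_trees(ann: AnnotationSet) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for key, e in ann.exon_items():
        trees.setdefault(e.chrom, IntervalTree()).addi(e.start, e.end, key)
    return trees


def count_features(
    alignments: Sequence[ReadAlignment],
    ann: AnnotationSet,
    min_overlap: int = 1,
) -> Tuple[Counter, Counter]:
    """Count unique alignments per exon key and per gene.

    A read increments every exon it overlaps by >= ``min_overlap`` bases and
    each gene at most once (unstranded).  Junction reads thus count for both
    flanking exons but once for the gene.
    """
    trees = _exon_trees(ann)
    exon_counts: Counter = Counter()
    gene_counts: Counter = Counter()
    for aln in alignments:
        genes_hit = set()
        exons_hit = set()
        for iv in aln.intervals:
            tree = trees.get(iv.chrom)
            if tree is None:
                continue
            for node in tree.overlap(iv.start, iv.end):
                if min(node.end, iv.end) - max(node.begin, iv.start) >= min_overlap:
                    exons_hit.add(node.data)
                    genes_hit.add(node.data[0])
        for key in exons_hit:
            exon_counts[key] += 1
        for gid in genes_hit:
            gene_counts[gid] += 1
    return exon_counts, gene_counts


def build_count_matrix(
    per_sample_counts: Dict[str, Counter],
    feature_ids: List,
    lengths: Dict,
) -> CountMatrix:
    sample_ids = list(per_sample_counts)
    counts = np.zeros((len(feature_ids), len(sample_ids)), dtype=np.int64)
    for j, sid in enumerate(sample_ids):
        c = per_sample_counts[sid]
        for i, fid in enumerate(feature_ids):
            counts[i, j] = c.get(fid, 0)
    return CountMatrix(
        feature_ids=feature_ids,
        sample_ids=sample_ids,
        counts=counts,
        lengths=np.array([lengths[f] for f in feature_ids]),
    )


def rpkm(count: float, feature_length_bases: float, total_mapped_reads: float) -> float:
    """Reads per kilobase of feature per million mapped reads."""
    if feature_length_bases <= 0 or total_mapped_reads <= 0:
        raise ValueError("feature length and library size must be positive")
    return count / (feature_length_bases / 1000.0) / (total_mapped_reads / 1e6)


def rpkm_matrix(cm: CountMatrix, totals: Optional[np.ndarray] = None) -> np.ndarray:
    if totals is None:
        totals = cm.counts.sum(axis=0)
    if (np.asarray(totals) <= 0).any():
        raise ValueError("library sizes must be positive")
    return cm.counts / (cm.lengths[:, None] / 1000.0) / (np.asarray(totals)[None, :] / 1e6)


# ---------------------------------------------------------------------------
# Junctions
# ---------------------------------------------------------------------------


def annotation_junctions(ann: AnnotationSet) -> Set[Tuple[str, int, int]]:
    out = set()
    for g in ann.genes:
        for t in g.transcripts:
            for chrom, donor, acceptor, _strand in t.junctions():
                out.add((chrom, donor, acceptor))
    return out


def observed_junctions(alignments: Sequence[ReadAlignment]) -> Set[Tuple[str, int, int]]:
    out = set()
    for aln in alignments:
        if len(aln.intervals) == 2:
            a, b = aln.intervals
            out.add((a.chrom, a.end, b.start))
    return out


def junction_coverage(ann: AnnotationSet, observed: Set[Tuple[str, int, int]]) -> float:
    """Fraction of observed junctions whose donor and acceptor both coincide
    with adjacent exon boundaries of some transcript."""
    if not observed:
        raise ValueError("empty observed junction set")
    annotated = annotation_junctions(ann)
    return sum(1 for j in observed if j in annotated) / len(observed)
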
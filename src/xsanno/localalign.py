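"""Stage 2: local-alignment conservation and paralog filtering.

Each exon surviving the reciprocal lift is aligned (seed-and-extend local
alignment) against both genomes.  Two measures summarise every hit:

* **PID** — percent identity per the UCSC milliBad formula,
* **PL** — the fraction of the exon (query) covered by the alignment.

The inter-species filter keeps an exon only when it has exactly one
qualifying hit on the other genome and that hit coincides with the lifted
(stage-1) location; the intra-species filter removes exons with a second
qualifying hit on their own genome (a conserved paralog that would cause
read multi-mapping).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from Bio import Align

from .model import GenomicInterval, SequenceStore, reverse_complement

log = logging.getLogger(__name__)

# Hit-reporting floor: qualifying thresholds never go below 0.90 in practice,
# and hits more than 0.02 below any floor can never qualify.
DEFAULT_MIN_PID = 0.88

# Shipped threshold defaults from the original study: inter-species PID/PL
# 0.95 for a close pair and 0.90 for a distant pair; intra-species PID 0.97
# and PL 0.95 for both.
INTER_CLOSE = (0.95, 0.95)
INTER_DISTANT = (0.90, 0.90)
INTRA_DEFAULT = (0.97, 0.95)


@dataclass(frozen=True)
class PidPlThresholds:
    inter_pid: float = 0.95
    inter_pl: float = 0.95
    intra_pid: float = 0.97
    intra_pl: float = 0.95

    def __post_init__(self):
        for v in (self.inter_pid, self.inter_pl, self.intra_pid, self.intra_pl):
            if not (0 < v <= 1):
                raise ValueError("thresholds must be in (0, 1]")


@dataclass(frozen=True)
class LocalAlignmentHit:
    matches: int
    mismatches: int
    q_gap_count: int
    q_gap_bases: int
    t_gap_count: int
    t_gap_bases: int
    q_start: int
    q_end: int
    target: GenomicInterval
    strand: str


def compute_pid(hit: LocalAlignmentHit) -> float:
    """Percent identity via the UCSC milliBad formula (non-mRNA variant)."""
    total = hit.matches + hit.mismatches
    if total == 0:
        raise ValueError("undefined PID: alignment has no aligned bases")
    q_ali = hit.q_end - hit.q_start
    t_ali = hit.target.length
    size_dif = abs(q_ali - t_ali)
    insert_factor = hit.q_gap_count + hit.t_gap_count
    milli_bad = 1000 * (
        hit.mismatches + insert_factor + round(3 * math.log(1 + size_dif))
    ) / total
    return (1000 - milli_bad) / 1000


def compute_pl(hit: LocalAlignmentHit, query_len: int) -> float:
    """Fraction of the query covered by the alignment."""
    if query_len <= 0:
        raise ValueError("query_len must be positive")
    return (hit.q_end - hit.q_start) / query_len


class SeedIndex:
    """Exact k-mer index over a genome for seeding local alignments."""

    def __init__(self, genome: SequenceStore, k: int = 12):
        self.genome = genome
        self.k = k
        self.kmers: Dict[str, List[Tuple[str, int]]] = {}
        for chrom, seq in genome.sequences.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                self.kmers.setdefault(kmer, []).append((chrom, i))

    def seed_hits(self, query: str) -> List[Tuple[str, int, int]]:
        """(chrom, genome_pos, query_pos) for every exact k-mer match."""
        out = []
        k = self.k
        for qpos in range(len(query) - k + 1):
            for chrom, gpos in self.kmers.get(query[qpos : qpos + k], ()):
                out.append((chrom, gpos, qpos))
        return out


def _candidate_windows(
    index: SeedIndex, query: str, band: int = 40
) -> List[Tuple[str, int, int]]:
    """Cluster seed hits by diagonal into candidate genome windows."""
    qlen = len(query)
    hits = index.seed_hits(query)
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, gpos, qpos in hits:
        by_chrom.setdefault(chrom, []).append((gpos - qpos, gpos))
    # one window per diagonal cluster: windows are NOT merged across
    # clusters, so co-located paralog copies each get their own alignment
    windows: List[Tuple[str, int, int]] = []
    for chrom, dh in by_chrom.items():
        dh.sort()
        cluster: List[int] = []
        for diag, _gpos in dh + [(10**15, 0)]:  # sentinel flush
            if cluster and diag - cluster[-1] > band:
                lo = max(0, cluster[0] - band)
                hi = min(index.genome.length(chrom), cluster[-1] + qlen + band)
                if hi - lo >= index.k:
                    windows.append((chrom, lo, hi))
                cluster = []
            cluster.append(diag)
    return sorted(set(windows))


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -7
    aligner.extend_gap_score = -2
    return aligner


_ALIGNER = _make_aligner()


def _hit_from_alignment(
    alignment, chrom: str, window_start: int, qlen: int, strand: str
) -> Optional[LocalAlignmentHit]:
    t_segs, q_segs = alignment.aligned
    if len(t_segs) == 0:
        return None
    target_seq = alignment.sequences[0]
    query_seq = alignment.sequences[1]
    matches = mismatches = 0
    q_gap_count = q_gap_bases = t_gap_count = t_gap_bases = 0
    prev_t_end = prev_q_end = None
    for (ts, te), (qs, qe) in zip(t_segs, q_segs):
        if prev_t_end is not None:
            dt = ts - prev_t_end
            dq = qs - prev_q_end
            if dq > 0:  # unaligned query bases: insertion in query
                q_gap_count += 1
                q_gap_bases += dq
            if dt > 0:  # unaligned target bases: insertion in target
                t_gap_count += 1
                t_gap_bases += dt
        for a, b in zip(target_seq[ts:te], query_seq[qs:qe]):
            if a == b:
                matches += 1
            else:
                mismatches += 1
        prev_t_end, prev_q_end = te, qe
    if matches + mismatches == 0:
        return None
    q_start, q_end = int(q_segs[0][0]), int(q_segs[-1][1])
    t_start, t_end = int(t_segs[0][0]) + window_start, int(t_segs[-1][1]) + window_start
    if strand == "-":  # report query offsets on the original orientation
        q_start, q_end = qlen - q_end, qlen - q_start
    return LocalAlignmentHit(
        matches=matches,
        mismatches=mismatches,
        q_gap_count=q_gap_count,
        q_gap_bases=q_gap_bases,
        t_gap_count=t_gap_count,
        t_gap_bases=t_gap_bases,
        q_start=q_start,
        q_end=q_end,
        target=GenomicInterval(chrom, t_start, t_end, "+"),
        strand=strand,
    )


def local_align(
    query: str,
    genome: "SequenceStore | SeedIndex",
    min_seed: int = 20,
    min_pid: float = DEFAULT_MIN_PID,
) -> List[LocalAlignmentHit]:
    """Seed-and-extend local alignment of a query against a genome.

    Returns every hit with aligned length >= ``min_seed`` and PID >=
    ``min_pid`` (a reporting floor slightly below any qualifying threshold).
    Deterministic; both strands are searched.
    """
    if len(query) < min_seed:
        log.info("query of length %d below min_seed %d: no hits", len(query), min_seed)
        return []
    index = genome if isinstance(genome, SeedIndex) else SeedIndex(genome)
    qlen = len(query)
    hits: List[LocalAlignmentHit] = []
    seen = set()
    for strand, q in (("+", query), ("-", reverse_complement(query))):
        for chrom, lo, hi in _candidate_windows(index, q):
            window = index.genome[chrom][lo:hi]
            alignments = _ALIGNER.align(window, q)
            # iterate lazily: co-optimal alignment counts can be astronomical
            alignment = next(iter(alignments), None)
            if alignment is None or alignments.score <= 0:
                continue
            hit = _hit_from_alignment(alignment, chrom, lo, qlen, strand)
            if hit is None:
                continue
            if hit.q_end - hit.q_start < min_seed:
                continue
            if compute_pid(hit) < min_pid:
                continue
            sig = (hit.target.chrom, hit.target.start, hit.target.end, hit.strand)
            if sig in seen:
                continue
            seen.add(sig)
            hits.append(hit)
    hits.sort(key=lambda h: (-(h.matches - h.mismatches), h.target.chrom, h.target.start))
    return hits


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def inter_species_filter(
    hits_on_sp2: Sequence[LocalAlignmentHit],
    query_len: int,
    wga_location: GenomicInterval,
    thr: PidPlThresholds,
) -> Tuple[bool, str]:
    """Keep an exon iff it has exactly one qualifying hit on the other genome
    and that hit overlaps the stage-1 lifted location on the same
    chromosome and strand."""
    qualifying = [
        h
        for h in hits_on_sp2
        if compute_pid(h) >= thr.inter_pid and compute_pl(h, query_len) >= thr.inter_pl
    ]
    if not qualifying:
        return False, "none_qualifying"
    if len(qualifying) > 1:
        return False, "multiple_qualifying"
    h = qualifying[0]
    if h.target.overlaps(wga_location) and h.strand == wga_location.strand:
        return True, "kept"
    return False, "location_mismatch"


def intra_species_filter(
    hits_on_own_genome: Sequence[LocalAlignmentHit],
    query_len: int,
    thr: PidPlThresholds,
) -> Tuple[bool, str]:
    """Drop an exon when a second qualifying hit exists on its own genome
    (the self-hit plus at least one conserved paralog)."""
    qualifying = sum(
        1
        for h in hits_on_own_genome
        if compute_pid(h) >= thr.intra_pid and compute_pl(h, query_len) >= thr.intra_pl
    )
    if qualifying >= 2:
        return False, "intra_paralog"
    return True, "kept"


@dataclass
class ExonAlignmentEvidence:
    """Per-exon alignment evidence the stage-2 filters consume."""

    query_len_sp1: int
    query_len_sp2: int
    wga_location: GenomicInterval
    inter_hits: List[LocalAlignmentHit]  # Sp1 exon vs Sp2 genome
    intra_hits_sp1: List[LocalAlignmentHit]  # Sp1 exon vs Sp1 genome
    intra_hits_sp2: List[LocalAlignmentHit]  # Sp2 exon vs Sp2 genome


def evaluate_exon(ev: ExonAlignmentEvidence, thr: PidPlThresholds) -> Tuple[bool, str]:
    keep, reason = inter_species_filter(
        ev.inter_hits, ev.query_len_sp1, ev.wga_location, thr
    )
    if not keep:
        return False, f"inter:{reason}"
    keep, reason = intra_species_filter(ev.intra_hits_sp1, ev.query_len_sp1, thr)
    if not keep:
        return False, f"intra_sp1:{reason}"
    keep, reason = intra_species_filter(ev.intra_hits_sp2, ev.query_len_sp2, thr)
    if not keep:
        return False, f"intra_sp2:{reason}"
    return True, "kept"


def collect_evidence(
    ann_sp1, ann_sp2, genome_sp1: SequenceStore, genome_sp2: SequenceStore,
    min_seed: int = 20,
) -> Dict:
    """Align every shared exon against both genomes once.

    The evidence is threshold-independent, so threshold selection can reuse
    it without re-aligning.
    """
    idx1 = SeedIndex(genome_sp1)
    idx2 = SeedIndex(genome_sp2)
    sp1_map = ann_sp1.exon_map()
    sp2_map = ann_sp2.exon_map()
    evidence = {}
    for key, iv1 in sp1_map.items():
        iv2 = sp2_map[key]
        seq1 = genome_sp1.fetch(iv1)
        seq2 = genome_sp2.fetch(iv2)
        evidence[key] = ExonAlignmentEvidence(
            query_len_sp1=len(seq1),
            query_len_sp2=len(seq2),
            wga_location=iv2,
            inter_hits=local_align(seq1, idx2, min_seed=min_seed),
            intra_hits_sp1=local_align(seq1, idx1, min_seed=min_seed),
            intra_hits_sp2=local_align(seq2, idx2, min_seed=min_seed),
        )
    return evidence


def la_filter(
    ann_sp1,
    ann_sp2,
    genome_sp1: SequenceStore,
    genome_sp2: SequenceStore,
    thr: PidPlThresholds = PidPlThresholds(),
    evidence: Optional[Dict] = None,
):
    """Apply the inter- and intra-species filters to a stage-1 annotation pair.

    Returns (filtered Sp1, filtered Sp2, per-exon reason dict).
    """
    if evidence is None:
        evidence = collect_evidence(ann_sp1, ann_sp2, genome_sp1, genome_sp2)
    reasons = {}
    keep = set()
    for key, ev in evidence.items():
        ok, reason = evaluate_exon(ev, thr)
        reasons[key] = reason
        if ok:
            keep.add(key)
    return ann_sp1.subset_exons(keep), ann_sp2.subset_exons(keep), reasons


def choose_thresholds(
    evidence: Dict,
    inter_grid: Sequence[float] = (0.90, 0.95, 0.97, 0.99),
    intra_grid: Sequence[float] = (0.90, 0.95, 0.97, 0.99),
) -> PidPlThresholds:
    """Grid-search PID/PL thresholds maximising retained exons.

    The inter-species pair and the intra-species pair are optimised
    separately; ties go to the stricter (larger) thresholds.
    """
    if not evidence:
        raise ValueError("no exons to optimise thresholds on")

    def best(pairs_scores):
        # max retained; tie -> lexicographically largest (pid, pl)
        m = max(s for _, s in pairs_scores)
        return max(p for p, s in pairs_scores if s == m)

    inter_scores = []
    for pid in sorted(inter_grid):
        for pl in sorted(inter_grid):
            thr = PidPlThresholds(inter_pid=pid, inter_pl=pl)
            n = sum(
                1
                for ev in evidence.values()
                if inter_species_filter(
                    ev.inter_hits, ev.query_len_sp1, ev.wga_location, thr
                )[0]
            )
            inter_scores.append(((pid, pl), n))
    inter_pid, inter_pl = best(inter_scores)

    intra_scores = []
    for pid in sorted(intra_grid):
        for pl in sorted(intra_grid):
            thr = PidPlThresholds(intra_pid=pid, intra_pl=pl)
            n = sum(
                1
                for ev in evidence.values()
                if intra_species_filter(ev.intra_hits_sp1, ev.query_len_sp1, thr)[0]
                and intra_species_filter(ev.intra_hits_sp2, ev.query_len_sp2, thr)[0]
            )
            intra_scores.append(((pid, pl), n))
    intra_pid, intra_pl = best(intra_scores)

    return PidPlThresholds(inter_pid, inter_pl, intra_pid, intra_pl)
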
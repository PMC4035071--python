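"""Stage 1: chain-based coordinate lifting with reciprocal filtering.

Exon intervals of the reference species (Sp1) are projected onto the second
species (Sp2) through a UCSC chain alignment, projected back, and kept only
when the round trip returns them to their exact original location.  The
``min_match`` parameter is the minimum fraction of an interval's bases that
must fall inside aligned chain blocks for a lift to succeed (the liftOver
``-minMatch`` semantics).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .formats import Chain, ChainAlignmentSet
from .model import AnnotationSet, ExonKey, GenomicInterval

# Shipped defaults selected by bootstrapping in the original study:
# 0.98 for a close species pair (human-chimpanzee), 0.913 for a more
# distant one (human-macaque).
MIN_MATCH_CLOSE = 0.98
MIN_MATCH_DISTANT = 0.913


@dataclass
class LiftResult:
    status: str  # ok | unmapped | split | below_min_match
    target: Optional[GenomicInterval] = None
    matched_fraction: float = 0.0


@dataclass
class ReciprocalFilterReport:
    exon_status: Dict[ExonKey, str] = field(default_factory=dict)
    transcript_status: Dict[Tuple[str, str], str] = field(default_factory=dict)

    def counts(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for s in self.exon_status.values():
            out[s] = out.get(s, 0) + 1
        return out


def _query_forward(chain: Chain, q_lo: int, q_hi: int) -> Tuple[int, int]:
    """Convert strand-local query range [q_lo, q_hi) to forward coordinates."""
    if chain.q_strand == "+":
        return q_lo, q_hi
    return chain.q_size - q_hi, chain.q_size - q_lo


def _walk_blocks(chain: Chain, start: int, end: int):
    """Yield (t_lo, t_hi, q_lo) for each aligned block piece inside [start, end).

    t coordinates are forward target positions, q_lo the strand-local query
    position aligned to t_lo.
    """
    t = chain.t_start
    q = chain.q_start
    for size, dt, dq in chain.blocks:
        t_hi = t + size
        if t_hi > start and t < end:
            lo = max(t, start)
            hi = min(t_hi, end)
            yield lo, hi, q + (lo - t)
        if t >= end:
            break
        t = t_hi + dt
        q = q + size + dq


def lift_interval(
    iv: GenomicInterval, chains: ChainAlignmentSet, min_match: float
) -> LiftResult:
    """Project one interval through the highest-scoring overlapping chain.

    Returns status ``ok`` with the image of the outermost aligned bases when
    at least ``min_match`` of the interval's bases fall in aligned blocks of
    that chain; ``below_min_match`` / ``split`` / ``unmapped`` otherwise.
    """
    if not (0 < min_match <= 1):
        raise ValueError("min_match must be in (0, 1]")
    candidates = [
        c
        for c in chains
        if c.t_name == iv.chrom and c.t_start < iv.end and iv.start < c.t_end
    ]
    if not candidates:
        return LiftResult("unmapped")
    best = max(candidates, key=lambda c: c.score)

    matched = 0
    first: Optional[Tuple[int, int]] = None  # (t_lo, q_lo) of first aligned base
    last: Optional[Tuple[int, int]] = None  # (t_hi, q_hi) past last aligned base
    for t_lo, t_hi, q_lo in _walk_blocks(best, iv.start, iv.end):
        matched += t_hi - t_lo
        if first is None:
            first = (t_lo, q_lo)
        last = (t_hi, q_lo + (t_hi - t_lo))
    fraction = matched / iv.length

    if fraction >= min_match and first is not None:
        q_fwd_start, q_fwd_end = _query_forward(best, first[1], last[1])
        strand = iv.strand if best.q_strand == "+" else ("-" if iv.strand == "+" else "+")
        target = GenomicInterval(best.q_name, q_fwd_start, q_fwd_end, strand)
        return LiftResult("ok", target, fraction)

    if len(candidates) > 1:
        # would the union of chains have covered it?
        covered = np.zeros(iv.length, dtype=bool)
        for c in candidates:
            for t_lo, t_hi, _ in _walk_blocks(c, iv.start, iv.end):
                covered[t_lo - iv.start : t_hi - iv.start] = True
        if covered.mean() >= min_match:
            return LiftResult("split", None, fraction)
    return LiftResult("below_min_match", None, fraction)


def reciprocal_convert(
    ann: AnnotationSet,
    chain_fwd: ChainAlignmentSet,
    chain_back: ChainAlignmentSet,
    min_match: float,
) -> Tuple[AnnotationSet, AnnotationSet, ReciprocalFilterReport]:
    """Lift every exon Sp1 -> Sp2 -> Sp1 and keep only exact round trips.

    Removal rules: an exon is removed if the forward lift fails, the back
    lift fails, or the back-lifted interval differs from the original by a
    single base; a transcript is removed outright when its surviving exons
    land on more than one Sp2 chromosome or strand.

    Returns (Sp2 annotation, Sp1 annotation filtered to the same exon keys,
    report).  The two annotations contain identical exon keys.
    """
    report = ReciprocalFilterReport()
    lifted: Dict[ExonKey, GenomicInterval] = {}

    for key, iv in ann.exon_items():
        fwd = lift_interval(iv, chain_fwd, min_match)
        if fwd.status != "ok":
            report.exon_status[key] = "failed_forward"
            continue
        back = lift_interval(fwd.target, chain_back, min_match)
        if back.status != "ok":
            report.exon_status[key] = "failed_back"
            continue
        if back.target != iv:
            report.exon_status[key] = "moved_on_lift_back"
            continue
        report.exon_status[key] = "kept"
        lifted[key] = fwd.target

    # transcript-level consistency on the Sp2 side
    by_tx: Dict[Tuple[str, str], List[ExonKey]] = {}
    for key in lifted:
        by_tx.setdefault((key[0], key[1]), []).append(key)
    for g in ann.genes:
        for t in g.transcripts:
            tx = (g.gene_id, t.transcript_id)
            keys = by_tx.get(tx, [])
            if not keys:
                report.transcript_status[tx] = "emptied"
                continue
            landings = {(lifted[k].chrom, lifted[k].strand) for k in keys}
            if len(landings) > 1:
                report.transcript_status[tx] = "chrom_strand_inconsistent"
                for k in keys:
                    report.exon_status[k] = "removed_chrom_strand_inconsistent"
                    del lifted[k]
            else:
                report.transcript_status[tx] = "kept"

    keep = set(lifted)
    ann_sp1 = ann.subset_exons(keep)
    ann_sp2 = ann.subset_exons(keep, relocate=lifted)
    return ann_sp2, ann_sp1, report


def select_min_match(
    ann: AnnotationSet,
    chain_fwd: ChainAlignmentSet,
    chain_back: ChainAlignmentSet,
    grid,
    n_boot: int = 100,
    fidelity_min: float = 0.99,
    seed: int = 0,
) -> float:
    """Choose min_match by bootstrapping the retention/fidelity trade-off.

    For each grid value, exons are resampled with replacement ``n_boot``
    times; the mean fraction of exons surviving the reciprocal filter
    (retention) and the mean fraction of forward-lifted exons whose back
    lift returns them exactly (fidelity) are recorded.  The returned value
    maximises retention among grid values whose fidelity is at least
    ``fidelity_min``; ties go to the larger (stricter) value.
    """
    grid = sorted(grid)
    if not grid or not all(0 < g <= 1 for g in grid):
        raise ValueError("grid must be nonempty with values in (0, 1]")

    # per-exon lift geometry is independent of min_match: precompute once
    f_fwd, f_back, exact = [], [], []
    for _key, iv in ann.exon_items():
        fwd = lift_interval(iv, chain_fwd, min_match=min(grid))
        if fwd.status != "ok":
            # retry at an epsilon threshold to recover the geometry even when
            # the fraction is below the smallest grid value
            fwd = lift_interval(iv, chain_fwd, min_match=1e-9)
        if fwd.status != "ok":
            f_fwd.append(0.0)
            f_back.append(0.0)
            exact.append(False)
            continue
        f_fwd.append(fwd.matched_fraction)
        back = lift_interval(fwd.target, chain_back, min_match=1e-9)
        if back.status != "ok":
            f_back.append(0.0)
            exact.append(False)
        else:
            f_back.append(back.matched_fraction)
            exact.append(back.target == iv)
    f_fwd = np.asarray(f_fwd)
    f_back = np.asarray(f_back)
    exact = np.asarray(exact)
    n = len(f_fwd)
    if n == 0:
        raise ValueError("annotation has no exons")

    rng = np.random.default_rng(seed)
    samples = rng.integers(0, n, size=(n_boot, n))
    retention: Dict[float, float] = {}
    fidelity: Dict[float, float] = {}
    for m in grid:
        fwd_ok = f_fwd >= m
        kept = fwd_ok & (f_back >= m) & exact
        ret, fid = [], []
        for idx in samples:
            fo = fwd_ok[idx]
            ke = kept[idx]
            ret.append(ke.mean())
            fid.append(ke.sum() / fo.sum() if fo.any() else 0.0)
        retention[m] = float(np.mean(ret))
        fidelity[m] = float(np.mean(fid))

    eligible = [m for m in grid if fidelity[m] >= fidelity_min]
    if not eligible:
        raise ValueError(
            "no grid value attains fidelity_min; fidelity curve: "
            + ", ".join(f"{m}:{fidelity[m]:.4f}" for m in grid)
        )
    best_ret = max(retention[m] for m in eligible)
    return max(m for m in eligible if retention[m] == best_ret)
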
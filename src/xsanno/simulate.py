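"""Stage 3a: equal-expression RNA-seq read simulation.

Single-end reads of fixed length are drawn uniformly from spliced transcript
sequences so that every transcript receives ``round(coverage * L / read_length)``
reads per lane — the equal-expression null under which any between-species
count difference reflects mappability alone.  Substitution errors are applied
per base at a constant rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .model import AnnotationSet, GenomicInterval, SequenceStore

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    read_length: int = 100
    coverage: float = 10.0
    n_lanes: int = 10
    error_rate: float = 0.002
    seed: int = 0

    def __post_init__(self):
        if self.read_length <= 0 or self.coverage <= 0:
            raise ValueError("read_length and coverage must be positive")
        if self.n_lanes < 2:
            raise ValueError("need >= 2 lanes per species for the differential test")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must be in [0, 1)")


@dataclass
class SimulatedRead:
    read_id: str  # "<transcript_id>|L<lane>|<serial>|<start offset>"
    sequence: str

    @property
    def transcript_id(self) -> str:
        return self.read_id.split("|")[0]

    @property
    def start_offset(self) -> int:
        return int(self.read_id.split("|")[3])


def transcript_sequences(
    ann: AnnotationSet, genome: SequenceStore
) -> Dict[str, str]:
    """Spliced transcript sequences, 5'->3' ('-' transcripts reverse-complemented)."""
    out: Dict[str, str] = {}
    for g in ann.genes:
        for t in g.transcripts:
            parts = []
            for i, e in enumerate(t.exons):
                if e.end > genome.length(e.chrom):
                    raise ValueError(
                        f"exon ({g.gene_id},{t.transcript_id},{i}) out of bounds"
                    )
                parts.append(genome[e.chrom][e.start : e.end])
            seq = "".join(parts)
            if t.strand == "-":
                from .model import reverse_complement

                seq = reverse_complement(seq)
            out[t.transcript_id] = seq
    return out


def reads_per_transcript(length: int, cfg: SimConfig, weight: float = 1.0) -> int:
    if length < cfg.read_length:
        return 0
    return int(round(cfg.coverage * length / cfg.read_length * weight))


def simulate_lane(
    transcripts: Dict[str, str],
    cfg: SimConfig,
    lane: int,
    expression: Optional[Dict[str, float]] = None,
) -> List[SimulatedRead]:
    """Simulate one lane of reads; deterministic per (cfg.seed, lane).

    ``expression`` optionally scales the per-transcript read number
    (default 1.0 for every transcript: the equal-expression null).
    Transcripts shorter than the read length are skipped.
    """
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, lane])
    reads: List[SimulatedRead] = []
    L = cfg.read_length
    for tx_id in sorted(transcripts):
        seq = transcripts[tx_id]
        weight = 1.0 if expression is None else expression.get(tx_id, 1.0)
        n = reads_per_transcript(len(seq), cfg, weight)
        if n == 0:
            continue
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        starts = rng.integers(0, len(seq) - L + 1, size=n)
        for serial, start in enumerate(starts):
            read = arr[start : start + L].copy()
            if cfg.error_rate > 0:
                err = np.nonzero(rng.random(L) < cfg.error_rate)[0]
                for pos in err:
                    choices = _BASES[_BASES != read[pos]]
                    read[pos] = choices[rng.integers(0, len(choices))]
            reads.append(
                SimulatedRead(f"{tx_id}|L{lane}|{serial}|{int(start)}", read.tobytes().decode())
            )
    return reads


def simulate_lanes(
    transcripts: Dict[str, str],
    cfg: SimConfig,
    expression_per_lane: Optional[List[Dict[str, float]]] = None,
) -> List[List[SimulatedRead]]:
    return [
        simulate_lane(
            transcripts,
            cfg,
            lane,
            None if expression_per_lane is None else expression_per_lane[lane],
        )
        for lane in range(cfg.n_lanes)
    ]


def truth_intervals(
    ann: AnnotationSet, transcript_id: str, offset: int, length: int
) -> Tuple[GenomicInterval, ...]:
    """Genomic footprint of a read at a transcript offset (spliced, strand-aware)."""
    for g in ann.genes:
        for t in g.transcripts:
            if t.transcript_id != transcript_id:
                continue
            tx_len = t.length
            if t.strand == "-":  # transcript coordinates run 3'->5' in genome order
                offset = tx_len - offset - length
            pieces = []
            pos = 0
            remaining_start = offset
            remaining_end = offset + length
            for e in t.exons:
                e_lo, e_hi = pos, pos + e.length
                lo = max(e_lo, remaining_start)
                hi = min(e_hi, remaining_end)
                if lo < hi:
                    pieces.append(
                        GenomicInterval(
                            e.chrom, e.start + (lo - e_lo), e.start + (hi - e_lo), t.strand
                        )
                    )
                pos = e_hi
            return tuple(pieces)
    raise KeyError(transcript_id)
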
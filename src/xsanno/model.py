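"""Core in-memory model: intervals, the gene/transcript/exon hierarchy, sequences.

All coordinates are 0-based half-open (BED-like) on a named chromosome.
Readers and writers of 1-based formats (GTF) convert at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, List, Optional, Tuple

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a chromosome, with strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


# Stable identity of an exon through every filtering stage.
ExonKey = Tuple[str, str, int]  # (gene_id, transcript_id, exon_index)


@dataclass
class TranscriptModel:
    transcript_id: str
    exons: List[GenomicInterval]

    def __post_init__(self) -> None:
        if self.exons:
            chroms = {e.chrom for e in self.exons}
            strands = {e.strand for e in self.exons}
            if len(chroms) > 1 or len(strands) > 1:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons span multiple "
                    f"chromosomes/strands ({chroms}, {strands})"
                )
            self.exons = _merge_sorted(self.exons)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def length(self) -> int:
        return sum(e.length for e in self.exons)

    def junctions(self) -> List[Tuple[str, int, int, str]]:
        """(chrom, donor, acceptor, strand) for each intron, donor < acceptor."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            out.append((self.chrom, a.end, b.start, self.strand))
        return out


def _merge_sorted(exons: List[GenomicInterval]) -> List[GenomicInterval]:
    """Sort exons and merge any that overlap or touch (rare in Ensembl)."""
    exons = sorted(exons, key=lambda e: (e.start, e.end))
    merged: List[GenomicInterval] = []
    for e in exons:
        if merged and e.start <= merged[-1].end:
            last = merged[-1]
            if e.end > last.end:
                merged[-1] = replace(last, end=e.end)
        else:
            merged.append(e)
    return merged


@dataclass
class GeneModel:
    gene_id: str
    transcripts: List[TranscriptModel]
    biotype: str = "protein_coding"

    @property
    def exonic_length(self) -> int:
        """Length of the union of all exon intervals of the gene."""
        ivs = sorted(
            ((e.chrom, e.start, e.end) for t in self.transcripts for e in t.exons)
        )
        total = 0
        cur_chrom, cur_start, cur_end = None, 0, 0
        for chrom, start, end in ivs:
            if chrom != cur_chrom or start > cur_end:
                total += cur_end - cur_start
                cur_chrom, cur_start, cur_end = chrom, start, end
            else:
                cur_end = max(cur_end, end)
        total += cur_end - cur_start
        return total


@dataclass
class AnnotationSet:
    """Gene -> transcript -> exon hierarchy on one genome assembly."""

    genes: List[GeneModel] = field(default_factory=list)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes)

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def gene_ids(self) -> List[str]:
        return [g.gene_id for g in self.genes]

    def counts(self) -> Tuple[int, int, int]:
        n_t = sum(len(g.transcripts) for g in self.genes)
        n_e = sum(len(t.exons) for g in self.genes for t in g.transcripts)
        return (len(self.genes), n_t, n_e)

    def exon_items(self) -> Iterator[Tuple[ExonKey, GenomicInterval]]:
        for g in self.genes:
            for t in g.transcripts:
                indices = getattr(t, "_exon_indices", None)
                for pos, e in enumerate(t.exons):
                    idx = indices[pos] if indices is not None else pos
                    yield (g.gene_id, t.transcript_id, idx), e

    def exon_map(self) -> Dict[ExonKey, GenomicInterval]:
        return dict(self.exon_items())

    def exonic_lengths(self) -> Dict[str, int]:
        return {g.gene_id: g.exonic_length for g in self.genes}

    def subset_exons(
        self,
        keep,
        relocate: Optional[Dict[ExonKey, GenomicInterval]] = None,
    ) -> "AnnotationSet":
        """New AnnotationSet keeping only exons whose key satisfies ``keep``.

        Exon keys are preserved verbatim (the index component refers to the
        position in the *original* transcript, so keys stay stable across
        stages).  ``relocate`` optionally substitutes new coordinates, which
        is how the lifted (Sp2) annotation is materialised.

        Transcripts emptied of exons, and genes emptied of transcripts, are
        dropped.
        """
        keep_set = keep if callable(keep) else (lambda k, s=set(keep): k in s)
        genes: List[GeneModel] = []
        for g in self.genes:
            new_ts = []
            for t in g.transcripts:
                kept: List[Tuple[int, GenomicInterval]] = []
                indices = getattr(t, "_exon_indices", None)
                for pos, e in enumerate(t.exons):
                    i = indices[pos] if indices is not None else pos
                    key = (g.gene_id, t.transcript_id, i)
                    if not keep_set(key):
                        continue
                    iv = relocate[key] if relocate is not None else e
                    kept.append((i, iv))
                if kept:
                    nt = TranscriptModel.__new__(TranscriptModel)
                    nt.transcript_id = t.transcript_id
                    nt.exons = [iv for _, iv in sorted(kept, key=lambda p: p[1].start)]
                    nt._exon_indices = [  # original indices, sorted to match exons
                        i for i, _ in sorted(kept, key=lambda p: p[1].start)
                    ]
                    new_ts.append(nt)
            if new_ts:
                genes.append(GeneModel(g.gene_id, new_ts, g.biotype))
        return AnnotationSet(genes)


class SequenceStore:
    """Chromosome name -> nucleotide string (A/C/G/T/N), with lengths."""

    def __init__(self, sequences: Dict[str, str]):
        self.sequences = {name: seq.upper() for name, seq in sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def lengths(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def fetch(self, iv: GenomicInterval) -> str:
        """Sequence of the interval in genome (+) orientation; revcomp if '-'."""
        seq = self.sequences[iv.chrom]
        if iv.end > len(seq):
            raise ValueError(f"interval {iv} beyond chromosome end {len(seq)}")
        sub = seq[iv.start : iv.end]
        return reverse_complement(sub) if iv.strand == "-" else sub
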
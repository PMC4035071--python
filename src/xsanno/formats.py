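"""Readers and writers for the standard formats the pipeline touches.

Internal coordinates are uniformly 0-based half-open; each reader converts
from its format's convention and each writer inverts that conversion exactly:

* GTF: 1-based inclusive -> subtract 1 from start.
* UCSC chain: already 0-based half-open; '-'-strand query coordinates are
  counted from the sequence end (kept verbatim in :class:`Chain`, resolved
  by the lifting code).
* PSL: 0-based half-open.
* BED: 0-based half-open.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .model import AnnotationSet, GeneModel, GenomicInterval, SequenceStore, TranscriptModel

log = logging.getLogger(__name__)


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf(path: str) -> AnnotationSet:
    """Parse an Ensembl-style GTF into the gene/transcript/exon hierarchy.

    Only ``exon`` features are consumed; exons lacking a transcript_id are
    rejected and logged.  Overlapping exons within a transcript are merged.
    """
    genes: Dict[str, Dict[str, List[GenomicInterval]]] = {}
    gene_order: List[str] = []
    transcript_order: Dict[str, List[str]] = {}
    biotypes: Dict[str, str] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated fields")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            attr = dict(_ATTR_RE.findall(attrs))
            gene_id = attr.get("gene_id")
            tx_id = attr.get("transcript_id")
            if not gene_id or not tx_id:
                log.warning("%s:%d: exon lacking gene_id/transcript_id, skipped", path, lineno)
                continue
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            iv = GenomicInterval(chrom, start_i - 1, end_i, strand)
            if gene_id not in genes:
                genes[gene_id] = {}
                gene_order.append(gene_id)
                transcript_order[gene_id] = []
                biotypes[gene_id] = attr.get("gene_biotype", "protein_coding")
            if tx_id not in genes[gene_id]:
                genes[gene_id][tx_id] = []
                transcript_order[gene_id].append(tx_id)
            genes[gene_id][tx_id].append(iv)

    out = []
    for gid in gene_order:
        ts = [TranscriptModel(tid, genes[gid][tid]) for tid in transcript_order[gid]]
        out.append(GeneModel(gid, ts, biotypes[gid]))
    return AnnotationSet(out)


def write_gtf(ann: AnnotationSet, path: str, source: str = "xsanno") -> None:
    with open(path, "w") as fh:
        fh.write("##provider: xsanno\n")
        for g in ann.genes:
            for t in g.transcripts:
                for e in t.exons:
                    attrs = (
                        f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}"; '
                        f'gene_biotype "{g.biotype}";'
                    )
                    fh.write(
                        f"{e.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f"{e.strand}\t.\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def read_fasta(path: str) -> SequenceStore:
    seqs: Dict[str, List[str]] = {}
    name: Optional[str] = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                name = line[1:].split()[0]
                if name in seqs:
                    raise ParseError(f"{path}: duplicate FASTA header {name!r}")
                seqs[name] = []
            elif line:
                if name is None:
                    raise ParseError(f"{path}: sequence before first header")
                seqs[name].append(line.strip())
    return SequenceStore({n: "".join(parts) for n, parts in seqs.items()})


def write_fasta(store: SequenceStore, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in store.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(reads: Iterable[Tuple[str, str]], path: str, quality_char: str = "I") -> int:
    """Write (read_id, sequence) pairs as Sanger FASTQ with constant quality."""
    n = 0
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{quality_char * len(seq)}\n")
            n += 1
    return n


def read_fastq(path: str) -> List[Tuple[str, str]]:
    reads = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+") or len(seq) != len(qual):
                raise ParseError(f"{path}: malformed FASTQ record at {header!r}")
            reads.append((header[1:].rstrip("\n"), seq))
    return reads


# ---------------------------------------------------------------------------
# UCSC chain
# ---------------------------------------------------------------------------


@dataclass
class Chain:
    """One UCSC chain: blockwise gapped alignment of target onto query.

    Coordinates are stored verbatim from the file: 0-based half-open on the
    forward strand for '+', counted from the sequence *end* for '-' strand
    (the UCSC convention).  ``blocks`` is a list of (size, dt, dq) with the
    final block carrying dt = dq = 0.
    """

    score: float
    t_name: str
    t_size: int
    t_strand: str
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    chain_id: str
    blocks: List[Tuple[int, int, int]]

    def validate(self) -> None:
        t_span = sum(b[0] + b[1] for b in self.blocks)
        q_span = sum(b[0] + b[2] for b in self.blocks)
        if t_span != self.t_end - self.t_start:
            raise ParseError(
                f"chain {self.chain_id}: target span {t_span} != "
                f"{self.t_end - self.t_start}"
            )
        if q_span != self.q_end - self.q_start:
            raise ParseError(
                f"chain {self.chain_id}: query span {q_span} != "
                f"{self.q_end - self.q_start}"
            )
        if any(b[0] <= 0 for b in self.blocks):
            raise ParseError(f"chain {self.chain_id}: non-positive block size")
        if self.blocks[-1][1] != 0 or self.blocks[-1][2] != 0:
            raise ParseError(f"chain {self.chain_id}: last block must have zero gaps")


@dataclass
class ChainAlignmentSet:
    chains: List[Chain]

    def __iter__(self):
        return iter(self.chains)

    def __len__(self):
        return len(self.chains)


def read_chain(path: str) -> ChainAlignmentSet:
    chains: List[Chain] = []
    header: Optional[List[str]] = None
    blocks: List[Tuple[int, int, int]] = []

    def flush():
        if header is None:
            return
        c = Chain(
            score=float(header[1]),
            t_name=header[2],
            t_size=int(header[3]),
            t_strand=header[4],
            t_start=int(header[5]),
            t_end=int(header[6]),
            q_name=header[7],
            q_size=int(header[8]),
            q_strand=header[9],
            q_start=int(header[10]),
            q_end=int(header[11]),
            chain_id=header[12] if len(header) > 12 else str(len(chains) + 1),
            blocks=list(blocks),
        )
        c.validate()
        chains.append(c)

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                flush()
                header = line.split()
                if len(header) < 12:
                    raise ParseError(f"{path}:{lineno}: short chain header")
                if header[4] != "+":
                    raise ParseError(f"{path}:{lineno}: target strand must be '+'")
                blocks = []
            else:
                parts = line.split()
                if header is None:
                    raise ParseError(f"{path}:{lineno}: block line before chain header")
                if len(parts) == 3:
                    blocks.append((int(parts[0]), int(parts[1]), int(parts[2])))
                elif len(parts) == 1:
                    blocks.append((int(parts[0]), 0, 0))
                else:
                    raise ParseError(f"{path}:{lineno}: bad block line {line!r}")
    flush()
    return ChainAlignmentSet(chains)


def write_chain(chains: ChainAlignmentSet, path: str) -> None:
    with open(path, "w") as fh:
        for c in chains:
            fh.write(
                f"chain {c.score:.0f} {c.t_name} {c.t_size} {c.t_strand} "
                f"{c.t_start} {c.t_end} {c.q_name} {c.q_size} {c.q_strand} "
                f"{c.q_start} {c.q_end} {c.chain_id}\n"
            )
            for size, dt, dq in c.blocks[:-1]:
                fh.write(f"{size} {dt} {dq}\n")
            fh.write(f"{c.blocks[-1][0]}\n\n")


# ---------------------------------------------------------------------------
# PSL (21-column) -> LocalAlignmentHit
# ---------------------------------------------------------------------------


def read_psl(path: str):
    """Parse 21-column PSL rows into LocalAlignmentHit objects keyed by qName.

    Allows substituting an external local aligner's output for the internal
    seed-and-extend aligner.
    """
    from .localalign import LocalAlignmentHit

    hits: Dict[str, List[LocalAlignmentHit]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("psLayout", "match", "-", " ")):
                continue
            f = line.split("\t")
            if len(f) != 21:
                raise ParseError(f"{path}:{lineno}: PSL needs 21 columns, got {len(f)}")
            strand = f[8]
            hit = LocalAlignmentHit(
                matches=int(f[0]),
                mismatches=int(f[1]),
                q_gap_count=int(f[4]),
                q_gap_bases=int(f[5]),
                t_gap_count=int(f[6]),
                t_gap_bases=int(f[7]),
                q_start=int(f[11]),
                q_end=int(f[12]),
                target=GenomicInterval(f[13], int(f[15]), int(f[16]), "+"),
                strand=strand[-1] if strand else "+",
            )
            hits.setdefault(f[9], []).append(hit)
    return hits


# ---------------------------------------------------------------------------
# BED junctions
# ---------------------------------------------------------------------------


def write_bed_junctions(
    junctions: Iterable[Tuple[str, int, int, str]], path: str, flank: int = 1
) -> None:
    """Write splice junctions as BED6 intervals flanking the intron.

    Each junction (chrom, donor, acceptor, strand) — donor/acceptor being the
    intron's half-open bounds — becomes a BED line spanning ``flank`` exonic
    bases on each side, named donor|acceptor.
    """
    with open(path, "w") as fh:
        for chrom, donor, acceptor, strand in sorted(junctions):
            fh.write(
                f"{chrom}\t{max(0, donor - flank)}\t{acceptor + flank}\t"
                f"JUNC|{donor}|{acceptor}\t0\t{strand}\n"
            )


def read_bed_junctions(path: str) -> List[Tuple[str, int, int, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, _s, _e, name, _score, strand = line.split("\t")[:6]
            _, donor, acceptor = name.split("|")
            out.append((chrom, int(donor), int(acceptor), strand.strip()))
    return out


# ---------------------------------------------------------------------------
# TSV count matrices
# ---------------------------------------------------------------------------


def write_counts_tsv(counts, path: str) -> None:
    counts.to_frame().to_csv(path, sep="\t")


def read_counts_tsv(path: str):
    import pandas as pd

    from .mapping import CountMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    lengths = df.pop("length")
    return CountMatrix(
        feature_ids=list(df.index),
        sample_ids=list(df.columns),
        counts=df.to_numpy(dtype=int),
        lengths=lengths.to_numpy(dtype=int),
    )
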
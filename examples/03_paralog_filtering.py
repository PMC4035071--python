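"""Local-alignment evidence: PID/PL of every hit and the two stage-2 filters.

Plants a 99%-identity copy of an exon elsewhere in the genome, aligns the
exon back against that genome and shows how percent identity (UCSC milliBad
formula) and percentage of aligned length feed the intra-species paralog
filter.
"""

import numpy as np

from xsanno.fixtures import plant_paralog
from xsanno.localalign import (
    PidPlThresholds,
    compute_pid,
    compute_pl,
    intra_species_filter,
    local_align,
)
from xsanno.model import SequenceStore

rng = np.random.default_rng(0)
genome = SequenceStore(
    {"chr1": "".join("ACGT"[i] for i in rng.integers(0, 4, size=2000))}
)
exon = genome["chr1"][400:600]  # a 200 bp exon

genome_with_copy, copy_locus = plant_paralog(
    genome, exon, identity=0.99, chrom="chr1", seed=1
)
print(f"planted a 99%-identity copy at {copy_locus}\n")

hits = local_align(exon, genome_with_copy)
print("hits of the exon against its own genome:")
for h in hits:
    print(f"  {h.target.chrom}:{h.target.start}-{h.target.end}  "
          f"matches={h.matches} mismatches={h.mismatches}  "
          f"PID={compute_pid(h):.3f}  PL={compute_pl(h, len(exon)):.3f}")

thr = PidPlThresholds()  # intra PID 0.97 / PL 0.95 - the shipped defaults
keep, reason = intra_species_filter(hits, len(exon), thr)
print(f"\nintra-species filter at PID>={thr.intra_pid}, PL>={thr.intra_pl}: "
      f"{'keep' if keep else 'drop'} ({reason})")
# Two qualifying hits (the self-hit plus the conserved copy) mean reads from
# this exon can multimap, so the exon is dropped from the ortholog model.
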
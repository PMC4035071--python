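"""Quantify the expression-comparison bias caused by mappability differences.

Simulates both species at identical expected expression (with lane-level
biological noise), maps reads to each genome, and compares the spread of
per-gene inter-species log2 fold changes for genes with a species-2-specific
high-identity paralog (DIM genes) against ordinary genes - once on mapped
counts and once on the generated (mapping-free) counts.
"""

from xsanno.fixtures import FixtureConfig, generate_pair
from xsanno.pipeline import PipelineConfig, bias_assessment
from xsanno.stats import exon_in_out_test, var_f_test

cfg = FixtureConfig(
    n_genes=40, n_paralog_sp2=8, paralog_identity=(0.995, 1.0), seed=17
)
bundle = generate_pair(cfg)

df = bias_assessment(
    bundle.annotation, bundle.genome_sp1, bundle.genome_sp2,
    bundle.chain_fwd, bundle.chain_back,
    PipelineConfig(seed=17), expression_noise_sd=0.2,
)

dim = set(bundle.truth.genes_of_class("paralog_sp2"))
fc_dim = df[df.gene_id.isin(dim)]
fc_con = df[~df.gene_id.isin(dim)]

mapped = var_f_test(fc_dim.fc_mapped, fc_con.fc_mapped)
truth = var_f_test(fc_dim.fc_truth, fc_con.fc_truth)

print(f"genes: {len(fc_con)} consistent, {len(fc_dim)} with a Sp2-only paralog\n")
print("one-sided F test, var(DIM log2FC) > var(consistent log2FC):")
print(f"  mapped counts:    F = {mapped.f_statistic:8.1f}   p = {mapped.p_value:.2e}")
print(f"  generated counts: F = {truth.f_statistic:8.2f}   p = {truth.p_value:.2f}")
# Mapped counts show a strongly inflated fold-change variance for DIM genes
# (their Sp2 reads multimap and are discarded), while the mapping-free
# measure shows none: the difference is pure mapping bias, which the
# pipeline's third stage removes from the annotation.
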
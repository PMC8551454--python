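"""Per-SNP association scan, genome-wide locus selection and window padding.

A strong simulated SNP effect reaches genome-wide significance
(p < 5e-8); the surrounding region is padded by +-250 kb (here +-3 kb to
match the toy panel's 1 kb spacing) and overlapping windows merge.
"""

from pleiopath import (
    SimulationConfig,
    extend_regions,
    scan_snps,
    select_gwas_loci,
    simulate_dataset,
)
from pleiopath.datatypes import LocusWindow

cfg = SimulationConfig(
    n_subjects=3000, n_snps=40, n_pleiotropic=3, true_model=0,
    beta_g_m=0.3, beta_g_y=0.6, outcome_type="binary", seed=5,
)
geno, pheno, truth = simulate_dataset(cfg)
summary = scan_snps(geno, pheno, "SS")
loci = select_gwas_loci(summary, threshold=5e-8)
print(summary.loc[summary.p.nsmallest(5).index, ["snp_id", "bp", "beta", "p"]]
      .to_string(index=False))
print(f"\ngenome-wide significant: {loci} (truth: {truth.pleiotropic_snps})")
peaks = [
    LocusWindow("1", int(bp), int(bp))
    for bp in summary.set_index("snp_id").loc[loci, "bp"]
]
for w in extend_regions(peaks, pad=3000):
    print(f"candidate window chr{w.chrom}:{w.start_bp}-{w.end_bp}")
# Windows carry the peak SNPs plus their LD neighbourhood into step 1.
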
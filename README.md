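# clonepop

Temporal population genomics for clonal haploid fungal cohorts — built for
the situation a biocontrol programme creates: an entomopathogenic fungus
(e.g. *Beauveria bassiana*) is mass-released against an insect pest, and
isolates are re-collected from the same site over decades. The questions the
package answers from a SNP matrix of those isolates:

* Which isolates are clones of each other, and of the released strains?
  How much of the field population do the released strains' descendants make
  up, and do clonal lineages persist or get replaced between decades?
* How diverse and differentiated are the temporal sub-populations (Tajima's
  *D*, Hudson's *F*<sub>ST</sub> in 5-kb windows), and does linkage
  disequilibrium decay like a recombining population or plateau like a
  clonal one?
* Where are selective sweeps, and are the swept regions enriched for
  transposable elements (TEs) and effector genes?
* Did the released strains outcross? Long runs of identical SNP calls
  (≥ 1500 consecutive sites) between a released strain and opposite
  mating-type (MAT) isolates, after excluding segments also conserved in
  same-MAT isolates, are counted as candidate crossover blocks.
* What admixture structure does the cohort carry (haploid-likelihood EM
  ancestry, *K* = 2–6)?

All analyses run on haploid biallelic SNP calls (VCF), an isolate metadata
table (TSV), and optional TE (BED) / gene (GFF3) annotations. A synthetic
cohort generator (`clonepop.simdata`) emits all of these files plus truth
tables, so the whole pipeline is testable without any sequencing data.

## Core statistics

For a haploid sample of size *n* with *S* segregating sites in a window,
Tajima's *D* = (π − *S*/a₁) / √(e₁S + e₂S(S−1)) with π the exact mean
pairwise difference count and a₁, e₁, e₂ the usual constants.
Hudson's *F*<sub>ST</sub> is combined across sites as a ratio of averages,
Σ[(p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1)] / Σ[p₁(1−p₂)+p₂(1−p₁)].
LD is the gametic r² over jointly observed haploid calls, binned by physical
distance after MAF ≥ 0.1 / call-rate ≥ 0.6 filtering and seeded subsampling.
The sweep scan computes a composite likelihood ratio on a 1-kb grid: each
site's derived-allele count is modelled under a star-approximation hard
sweep in which a lineage at distance *d* escapes with probability
1 − exp(−α·d), against the genome-wide background site-frequency spectrum;
the top 5% of windows are called swept. Ancestry maximises
∏ᵢ∏ₗ [Σₖ q<sub>ik</sub> f<sub>kl</sub>]^g · [Σₖ q<sub>ik</sub>(1−f<sub>kl</sub>)]^(1−g)
by EM (one Bernoulli draw per haploid locus).

## Worked example

```python
import clonepop as cp

cfg = cp.SimConfig(n_chromosomes=3, chrom_length=400_000,
                   n_isolates_per_epoch={1997: 10, 2007: 10, 2017: 10},
                   n_founder_lineages=8, mutation_rate=8e-4,
                   group_mutation_rate=8e-4, seed=1)
out = cp.simulate_cohort(cfg, "cohort/")          # VCF, TSV, BED, GFF3, truth

rep = cp.run_pipeline(cp.RunConfig(
    vcf=str(out.vcf), meta=str(out.meta_tsv), te_bed=str(out.te_bed),
    genes_gff=str(out.genes_gff), mat_fasta=str(out.mat_fasta),
    out_dir="results/", ancestry_k=[2], ancestry_seeds=2,
    ancestry_max_iter=300, ld_subsample_n=8))
print(rep["recovery_rates"], rep["median_fst"], rep["sweeps"])
```

prints (seed 1):

```
{'Bb13': {'n_clone': 9, 'n_total': 30, 'percent': 30.0},
 'Bb17': {'n_clone': 2, 'n_total': 30, 'percent': 6.7}}
{'1997-2007': 0.0895, '1997-2017': 0.1536, '2007-2017': 0.1266}
{'n_selected': 60, 'te_overlap': {'n_overlap': 40, 'n_total': 60, 'percent': 67},
 'effectors': {'n_effector': 2, 'n_genes': 33, 'percent': 6.06}}
```

i.e. 9 of the 30 field isolates are clone-mates of released strain Bb13 (a
30% recovery rate in this small cohort), the decadal populations sit around
Wright's moderate-differentiation band (*F*<sub>ST</sub> 0.05–0.15), and 67%
of the top-CLR windows fall in TE compartments (the planted sweep was placed
inside one). The same stages are exposed on the command line
(`clonepop simulate|run|filter|clonal|stats|sweep|recomb|ancestry`).

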
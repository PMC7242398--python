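# Methods

## Scope and data model

All analyses operate on a `GenotypeMatrix`: isolates × ordered biallelic SNP
sites with haploid calls in {0 = ref, 1 = alt, −1 = missing}. The organism is
a haploid heterothallic ascomycete; diploid-coded VCF genotypes are collapsed
(`0/0`→0, `1/1`→1) and heterozygous calls are set missing with a logged
count, since a haploid nucleus cannot be heterozygous (isolates carrying both
MAT idiomorphs are handled separately as putative heterokaryons by the MAT
typer). Sites inside a declared MAT-locus interval can be excluded on read —
the idiomorphic region does not align between mating types, so calls there
are unreliable. Internal coordinates are 1-based (VCF/GFF convention); BED
input is converted from 0-based half-open on read. No MAF or call-rate
filter is applied by default; the LD stage applies MAF ≥ 0.1 and call rate
≥ 0.6 (the parameters conventionally used for haplotype-based LD estimation),
and both are configurable.

## Clonal delineation

The pairwise statistic is SNP-matrix identity: the fraction of jointly
non-missing sites with equal calls. Over a dense genome-wide site set this
is an assembly-free proxy for average nucleotide identity (ANI); we use it
because assembling every isolate is out of scope and, at ~10⁵–10⁶ biallelic
sites, matrix identity carries the same clonality signal. Thresholds are
configurable: identity > 0.998 delimits clonal groups, > 0.99 deeper
lineages. Clustering is single linkage (connected components of the
above-threshold graph) because clonal descent produces subclades, not
centroid-shaped clusters; ties at exactly the threshold are *not* joined
(strict >). Groups of ≥ 2 isolates are labelled C1… in decreasing size;
everything else stays a singleton. The NJ tree (Saitou–Nei, via scikit-bio)
uses distance = 1 − identity, with negative branch lengths clamped to 0 and
lowest-index tie-breaking as implemented by the library. PCA imputes missing
calls to the site mean and scales each site by 1/√(p(1−p)) — the
drift-variance normalisation standard for SNP PCA — then takes the SVD.

MAT typing searches the four idiomorph PCR primer sequences (forward primer
and reverse-complemented reverse primer) on both strands with ≤ 1 edit
(edlib); an idiomorph is present when both of its probes hit, and isolates
hitting both idiomorphs are reported as `both` (putative heterokaryon).

## Windowed statistics

Windows are non-overlapping tiles (default 5 kb, step = size, configurable);
one value per window, with per-chromosome and genome medians reported.

* **Tajima's D**: π is the exact mean pairwise difference count (summed
  per-site as 2k(m−k)/(m(m−1)) over m non-missing calls), θ_W = S/a₁, and D
  uses the standard 1989 constants computed at the population sample size.
  Windows with S = 0 are undefined (NaN).
* **Hudson's F_ST**: per-site numerator (p₁−p₂)² − p₁(1−p₁)/(n₁−1) −
  p₂(1−p₂)/(n₂−1) and denominator p₁(1−p₂)+p₂(1−p₁), combined per window as
  a ratio of averages. This estimator was chosen for its low small-sample
  bias and clean haploid interpretation; negative windows are retained, and
  Wright's moderate-differentiation band [0.05, 0.15] is exported as a
  constant for annotation. Sites with < 2 observed calls in either
  population are skipped.
* **LD decay**: r² from haplotype counts over jointly non-missing isolates,
  all intra-chromosomal pairs within 200 kb, averaged in 500-bp bins plus a
  1-bp-resolved profile of the first 100 bp. Because LD is sample-size
  sensitive, populations are first subsampled to a common size with a seeded
  generator. D′ is not computed.
* **DAF spectra**: 1-D (sweep background) and 2-D (population-pair) derived
  allele count spectra. Polarization defaults to reference-as-ancestral —
  a deliberate, imperfect convention, flagged here because no outgroup
  is bundled; an outgroup isolate id can be supplied instead, and
  unpolarizable sites are skipped and counted. The sweep scan can also run
  on the folded spectrum to soften mispolarization.

## Sweep scan

The scan is a composite-likelihood-ratio test in the SweepFinder tradition,
re-derived for this package rather than wrapping the published tool: at each
1-kb grid point x and sweep strength α, a site at distance d has per-lineage
escape probability p_e = 1 − exp(−α·d). Under the star-genealogy
approximation, K ~ Binom(n, p_e) lineages escape as a uniform subset of a
background configuration (derived count j₀ drawn from the genome-wide
spectrum, so the escaped subset's derived count is hypergeometric), while
the n−K swept lineages all inherit the sweeping haplotype's allele (derived
with probability j₀/n). CLR(x) = 2·[max_α Σ log P_sweep − Σ log P_bg],
clamped at 0; as p_e → 1 the model collapses onto the background exactly, so
far grid points score 0. Monomorphic sites present in the matrix are
modelled (the invariant-class mass is estimated from the data and the
spectrum floor is 10⁻⁶), because local fixation is the strongest footprint
of a recent sweep. Derived counts at sites with missing calls are rescaled
to the full sample size. The α grid defaults to 16 log-spaced values
spanning p_e ≈ 0.01–0.99 at the median inter-site distance; escape
probabilities are discretised to 48 levels (dense near 1) to cache the
emission table; distance is physical (uniform recombination assumed). The
top 5% quantile of grid windows is called swept: the cut is the ⌈qN⌉-th
largest CLR, ties included (all-tied inputs select everything, with a
warning). TE overlap counts a window as hit by ≥ 1 shared bp; effector
content is the fraction of effector-flagged genes among genes overlapping
selected windows (effector flags are an input annotation — effector
prediction itself is out of scope).

## Recombinant blocks

A block is a maximal run of consecutive sites (site-table order) with
identical non-missing calls between two isolates, kept when ≥ `min_snps`
(default 1500, ≈ 5 kb at the emulated density; a stricter variant of the
">1000 consecutive SNPs" convention — the flag `--min-snps` exposes both).
Missing calls terminate runs by default (conservative); `skip_missing=True`
instead bridges them without counting them. Because a released strain cannot
outcross with its own mating type, blocks it shares with same-MAT
*non-clonal* isolates are treated as ancestrally conserved sequence: their
interval union is subtracted from the candidates found against each
opposite-MAT isolate (any-overlap exclusion by default; a minimum
overlapping-fraction policy is available). The released strain's own clonal
group must be excluded from the background set — clone mates are identical
genome-wide and would blanket every candidate; this is the only reading
under which the analysis is non-degenerate. Block counts per opposite-MAT
partner are compared between the two released strains with a two-sided
two-sample t-test (Welch by default, Student optional); the degenerate
zero-variance cases return p = 1 (equal means) or p = 0 with a warning.
A Hudson–Kaplan four-gamete R_min scan (greedy interval stabbing over
incompatible site pairs) is provided as a windowed recombination signal;
population-scaled recombination-rate (ρ) estimation is out of scope.

## Haploid ancestry

The admixture likelihood uses one Bernoulli draw per haploid locus —
L = ∏ᵢ∏ₗ [Σₖ q_ik f_kl]^g·[Σₖ q_ik(1−f_kl)]^(1−g) — rather than the diploid
binomial of the classic programs, which would double-count haploid
observations. EM alternates source-population responsibilities with
closed-form Q and F updates; missing calls are skipped, F is clamped to
[10⁻⁶, 1−10⁻⁶], and the log-likelihood trace is stored (non-decreasing by
construction, asserted in tests). Defaults: tol 10⁻⁶ on ΔlogL, 10,000 max
iterations, 5 random restarts keeping the best likelihood. K = 1 is the
closed-form binomial fit. Label switching between restarts is resolved by
greedy matching on ancestral-frequency correlation. A fit is flagged
degenerate when a component carries < 1% of total ancestry mass or two
components collapse onto the same frequencies (then Q is not identifiable —
the flag fires on cohorts of identical isolates).

## Synthetic cohorts

`simulate_cohort` emulates a two-decade biocontrol survey: three temporal
sub-populations drawn from founder lineages with ~70% decadal turnover and
one lineage persisting through all epochs; two released MAT1-2 strains that
*are* the founders of their lineages, with clonal field descendants; TE
compartments (3 per chromosome) containing effector-enriched genes; a
planted hard sweep centred in a TE compartment; and recombinant blocks
copied verbatim from a released strain into opposite-MAT recipients.
Genealogy is a nested star (ancestral groups → founders → isolates) under
infinite sites: every mutation hits a fresh position, so the site matrix is
a perfect phylogeny and carries **no** four-gamete signal unless blocks or
sweeps are planted — which is exactly what makes planted-signal tests sharp.
Sites are therefore singletons at the lineage/group level; the generator
does not reproduce a coalescent frequency spectrum, background LD decay, or
gene conversion, so passing tests demonstrate correct *recovery of planted
structure*, not calibration on real data. Default parameters describe the
emulated system (12 chromosomes × 2.9 Mb ≈ 35 Mb genome, 152 field isolates,
24 founder lineages, ~10⁶ SNPs, 1% missing data, clone divergence 2×10⁻⁴ so
clone mates sit at ≈ 99.98% identity, balanced mating types decorrelated
from the two ancestral groups); tests and the acceptance script run
scaled-down cohorts (2–3 chromosomes of 0.25–0.4 Mb, ~25–30 isolates,
~10⁴ SNPs) chosen so every planted feature remains resolvable.

Two generator choices exist purely to make truth recovery exact rather than
probabilistic: planted blocks force a mismatching call at their two flanking
sites (otherwise the recovered run could extend past the planted boundary
whenever donor and recipient happen to agree there), and missing-data
injection skips block sites for the two isolates involved (a single missing
call would split the run under the default strict-run definition).

Neutral-equilibrium, panmictic and split-population cohorts cannot come from
the star model; `simulate_neutral` / `simulate_split` wrap msprime's haploid
coalescent (with recombination, so windows decorrelate — without it a single
genealogy makes window medians wander), and `simulate_admixture` draws
genotypes directly from the admixture likelihood with known Q and a fixed
ancestral-frequency divergence. Calibration-style checks (genome-median
Tajima's D within ±0.3 of 0; panmictic median F_ST within ±0.05; clonal LD
plateau above half its short-range value while recombining cohorts decay
below) run on these generators at fixed seeds.

## Numerical conventions and limitations

Windows with no usable sites are NaN, never 0. Pairs with zero joint
coverage have undefined identity and are treated as below any clustering
threshold. Percentages are rounded as reported downstream (recovery rates
to 1 decimal, TE overlap to integer, effector fractions to 2 decimals).
All stochastic steps flow from explicit integer seeds; the pipeline derives
a deterministic child seed per stage so stages re-run independently.
Known limitations: reference-based polarization biases the DAF spectra and
unfolded sweep background when the reference allele is not ancestral (use an
outgroup or the folded mode); the CLR model ignores recombination-map
heterogeneity and the background-allele correlation among escaped lineages
beyond the hypergeometric subset approximation; block detection has no
tolerance for isolated genotyping errors inside a run unless
`skip_missing`/relaxed thresholds are used; ancestry K is not selected
automatically (no cross-validation).
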
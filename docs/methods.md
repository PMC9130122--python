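# Methods

## Statistical model

Each testable unit is one SNP in one genotype. Genotyping of a mixed-ploid
individual yields integer allele dosages (α reference copies, β alternative
copies; α + β = the locus ploidy, which varies across loci in aneuploid
genomes). The null hypothesis is that the expressed reference-allele
proportion θ equals the relative genomic dosage P = α/(α+β).

Replicate RNA-Seq counts are y_r ~ Binomial(n_r, θ) with prior
θ ~ Beta(α, β). Because the Beta prior is conjugate, the posterior is
Beta(a, b) with a = α + Σ y_r and b = β + Σ (n_r − y_r); replicates enter
only through their sums, so testing pooled counts is *exactly* equivalent to
testing per-replicate counts, and the identity a + b = α + β + Σ n_r holds
in exact integer arithmetic (the implementation only converts to float
inside the quantile routines).

Using the dosages as prior pseudo-counts centers the prior at P with weight
equal to the ploidy. At realistic RNA depths (hundreds of reads) the data
dominate; at low depth the prior pulls toward the null, which makes the test
conservative rather than anticonservative.

The decision rule: the unit shows ASE iff P lies strictly outside the
highest-density interval (HDI) of Beta(a, b) at credibility mass 1 − ζ/N.
A value exactly on an HDI endpoint is *not* called ASE (closed interval —
the conservative reading). Direction is ref-biased when the pooled expressed
fraction exceeds P, alt-biased otherwise. A gene is an ASEG for a genotype
iff ≥ 1 of its tested SNPs in that genotype is ASE.

### The multiplicity correction

ζ is the desired significance level (default 0.05) and N the number of
effectively independent tests; the credibility mass 1 − ζ/N widens the HDI
the way a Bonferroni correction shrinks a rejection threshold. The default
N = 1000 reflects a panel of roughly a thousand independently tested genes
per genotype; N is a plain parameter, so callers can set it to the number of
genes actually tested. Because HDIs are nested in the mass, raising N can
only remove ASE calls, never add them. ζ is global, not recomputed per
genotype.

### HDI computation

For a > 1 and b > 1 the posterior is interior-unimodal and the HDI is the
narrowest quantile interval: the width Q(p + mass) − Q(p) is minimized over
the lower-tail probability p ∈ [0, 1 − mass] by bounded scalar optimization
(Brent; xatol 1e−12), where Q is the Beta quantile function. By
construction the achieved mass is exact up to quantile precision (≪ 1e−8).
Monotone-density edge cases attach to the boundary: a ≤ 1 < b gives
[0, Q(mass)], b ≤ 1 < a gives [Q(1 − mass), 1]. When a ≤ 1 and b ≤ 1 the
density is flat or bimodal, the HDI is not unique, and the central
(equal-tailed) interval is returned with a warning.

The test suite cross-checks the optimizer against an independent grid search
over p. The grid runs a 1e−5-resolution coarse pass plus two 100× local
refinement passes: in the far tails the quantile slope 1/f(Q(p)) amplifies
grid error in p by orders of magnitude, so a single coarse pass can locate
the optimal interval but not pin its endpoints tightly.

## Filtering cascade

In order (each step logged): (1) drop sites where every genotype is
homozygous or missing; (2) drop indel sites; (3) mask any call whose
estimated ploidy falls outside the accepted window (default 6–14) as
missing — genotypes are tested independently, so one aberrant call should
not discard the site for the others — and drop sites left without a
heterozygous call; (4) keep SNP×genotype units that are heterozygous
(1 ≤ α ≤ ploidy − 1), supported by ≥ 10 genomic (GBS) reads for that
genotype's call, and with pooled RNA-Seq total Σ n_r ≥ 10.

The four predicates are mutually independent, so the retained set is
invariant to application order (asserted by permutation in the tests). The
RNA minimum is applied to the pooled replicate total rather than per
replicate — pooling is the posterior's sufficient statistic — and the
threshold is switchable (`min_rna_reads`). Genomic depth is per genotype,
not summed across the panel.

## Synthetic panels

The generator emulates the targeted study design: K genotypes × R
replicates (defaults 6 × 3); SNP counts per transcript Poisson with mean 4;
per-call ploidy drawn from a 6–14 spectrum with a dodecaploid mode;
reference dosage uniform on {0..ploidy} (0 and ploidy = homozygous); a
configurable fraction of calls missing (default 5%) and of sites indels
(default 5%). For an `ase_fraction` (default 10%) of heterozygous
SNP×genotype pairs the true θ deviates from P, either by a fixed target
value or by a shift on the log-odds scale with random sign (default: logit
shift of 1.5 — a clearly biological-scale imbalance, e.g. 0.50 → 0.82).
All other pairs have θ = P exactly, so truth flags are consistent by
construction.

Read depths (GBS and per-replicate RNA totals) are negative binomial,
parameterized by mean and dispersion k (variance m + m²/k, default k = 2) to
mimic the overdispersion of reduced-representation and RNA sequencing;
defaults are 30× genomic and 100× RNA per replicate. One seed drives the
fixture through fixed per-stage substreams, so each stage is independently
regenerable and fixtures are byte-identical across runs.

What the generator does **not** model: read-level artifacts (mapping bias,
multimapping between homoeologs, restriction-site sampling of GBS),
dosage-estimation error (dosages are taken as true), correlation between
neighboring SNPs on a transcript, and any empirical dosage spectrum beyond
the uniform draw. Passing tests therefore demonstrate the statistical
machinery under the stated sampling model, not robustness to alignment or
genotyping artifacts in real data.

## Summaries and enrichment

ASEG intersections are reported as the exact-membership (exclusive)
partition over all 2^K − 1 genotype subsets, guarded to K ≤ 10. Genotype
dissimilarity is Euclidean distance between per-SNP vectors (relative
dosage P or relative expression; all SNPs or ASE-only), computed over
pairwise-complete SNPs, followed by average-linkage (UPGMA) clustering with
genotypes pre-sorted by name for deterministic ties; metric and linkage are
fixed choices, exposed as data (distance matrix + Newick) rather than
rendered figures. GO-term frequency tables count, per term, tested genes
and ASEGs per genotype, plus genes that are ASEGs in *every* genotype where
they were tested versus genes exclusive to a single genotype.

Enrichment uses the hypergeometric upper tail per GO term (selected = ASEGs,
background = all tested genes) with Benjamini–Hochberg adjustment across
terms at FDR 5%. This is a deliberate substitution for length-bias-aware
(Wallenius) testing: transcript-length bias weights are not available here,
and the interface leaves room for a weight vector should they become so.

## Problem sizes and numerical checks

The shipped statistical checks use: 10,000 null units (mixed ploidy, pooled
RNA ≈ 300) for the type-I rate, whose observed rejection fraction is ~1e−4
— far below ζ/N = 5e−5 per-test nominal would suggest because the integer
counts and prior shrinkage are both conservative; 2,000 shifted units
(pooled RNA ≈ 900) for power and posterior-mean RMSE; 150 random Beta
shapes for HDI optimizer-vs-grid agreement. These sizes give stable
two-decimal estimates of the rates involved while keeping the default suite
fast.

## Known limitations

- Strictly biallelic: multi-allelic records are refused, not split.
- Dosages are trusted as given; uncertainty from dosage calling is not
  propagated into the prior.
- θ is assumed shared across replicates (no replicate-level overdispersion
  term in the likelihood); strong replicate heterogeneity would inflate
  confidence.
- The HDI of the *Beta posterior* is tested against P; no posterior
  predictive (Beta-Binomial count-scale) interval is offered.
- GO terms are used as mapped; no DAG propagation.
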
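# Methods

## Scope

`cldla` implements the computational core of a recessive-disease
fine-mapping study in a closed livestock population: a variance-component
likelihood-ratio scan over haplotype-based locus-IBD matrices (cLDLA),
case–control homozygosity mapping with phenocopy diagnostics, common
disease-haplotype extraction, carrier-concordance filtering of candidate
sequence variants, and allele-frequency monitoring.  Every stage runs on
synthetic pedigreed data from the built-in gene-dropping simulator, which
supplies exact identity-by-descent (IBD) ground truth.

## Phenotype encoding

Diagnostic evidence maps deterministically onto the quantitative
phenotype **y**: free 1.0; progeny-confirmed carrier 2.0 (an animal with
at least two affected offspring of verified parentage is an obligate
heterozygote); pathologically confirmed affected 3.0.  Clinically
diagnosed animals without pathological confirmation receive interpolated
codes by strength of pedigree evidence: confirmed carrier ancestors on
both sides within two generations 2.75; a gap of three or more
generations 2.5; a single official carrier 2.25; missing pedigree 2.0.
The classification of an animal into an evidence class is the caller's
responsibility (the pedigree interpretation behind these classes is
ambiguous enough that automating it would hide a judgement call).

## Quality control

SNP exclusion applies, in order: missingness above 5 %; Mendelian
conflict rate above 1 % across checkable parent–offspring comparisons
(opposite-homozygote pairs, plus the trio check that two homozygous
parents determine the offspring genotype) — the published criterion
"frequent paternity conflicts" is unquantified, so the 1 % rate is this
package's operationalisation, configurable; missing map position;
observed heterozygosity below 0.05 (observed rather than expected,
computed over non-missing genotypes, because it is the simpler audit);
off-target chromosome.  Each SNP receives the first applicable reason
only, so drop reports are stable.  Animals below 0.95 call rate are
flagged but never removed.  Coordinates are 1-based; intervals are
closed on both ends except in BED output (0-based half-open, noted in
the file header).

## Relationship matrices and stratification control

The genome-wide unified additive relationship (UAR) matrix uses the
standard SNP-based estimator with per-SNP standardisation by
2p(1−p); missing genotypes are mean-imputed (dosage 2p) for this
computation only.  Its eigendecomposition supplies principal components
used as fixed covariates.  The retained count defaults to Horn's
parallel analysis: each SNP column is permuted independently across
animals, the UAR spectrum is rebuilt per replicate, and components whose
observed eigenvalue exceeds the 95th percentile of the permuted
eigenvalues at the same rank are retained.  On LD-rich single-chromosome
panels the permutation null destroys LD and the procedure retains
aggressively (around 40 of 160 components on the simulated data); an
explicit `n_pcs` override is therefore part of the interface.

## Locus IBD and diplotype relationship matrices

Windows of 40 consecutive SNPs slide one SNP at a time; the tested
position is the window midpoint, between the 20th and 21st SNP (floor of
the mean physical position, mean genetic position).  For two haplotypes
the IBD probability at the midpoint is the two-hypothesis closed form

    p = φ s / (φ s + (1 − φ) c)

with prior φ = 1 − (1 − 1/(2 Ne))^T (defaults Ne = 100, T = 10, giving
φ ≈ 0.049, typical for a livestock base population), survival
s = exp(−2 T d) where d is the genetic length spanned by the maximal
identity-by-state (IBS) runs immediately left and right of the midpoint,
and chance term c = Π (f_i² + (1 − f_i)²) over the run markers.  With no
flanking IBS the probability equals the prior; with long unbroken runs
on a dense map it approaches 1.  This estimator is a deliberately
self-contained stand-in for published multi-marker IBD recursions — it
reproduces their qualitative behaviour from the same three ingredients —
and is pluggable behind the `locibd_pair`/`locibd_matrix` interface.
The matrix builder vectorises the computation exactly (bit-packed
half-windows; run length = lowest set bit of the pairwise XOR) and is
property-tested against the scalar form.

Conversion to the diplotype relationship matrix (DRM) is the four-term
average: D_jk = ½ Σ over the four haplotype pairings for animals j ≠ k,
and D_jj = 1 + M[j1, j2].  If the smallest eigenvalue falls below 1e-6 a
minimal diagonal ridge is added and logged; inside the scan the
equivalent eigenvalue lift happens in the REML routine, which
decomposes D anyway.

## REML scan, threshold, support intervals

The restricted log-likelihood is profiled over the variance ratio
γ = σ_q²/σ_e²:

    l_R(γ) = −½ [ (n−p) log σ̂_e²(γ) + log|I + γD|
                  + log|X' (I + γD)^{-1} X| + (n−p) ]

computed on the eigenbasis of D, maximised by a log-spaced grid over
γ ∈ [1e-6, 1e3] (γ = 0 always evaluated) with golden-section refinement
to 1e-6 relative tolerance.  The null model is the closed-form OLS fit
under the same constant convention, computed once per scan since it has
no window terms.  LRT = max(0, 2(l_H1 − l_H0)) is referred to a χ²(1)
threshold at a Bonferroni-corrected level (0.001 of the family-wise
budget divided by the number of windows); because σ_q² is constrained to
the boundary, the true null is a 50:50 mixture of χ²₀ and χ²₁ and the
χ²₁ convention is conservative — null calibration is exercised in the
acceptance suite.  Support intervals use the LOD drop-off rule: from
each peak above threshold, extend through consecutive windows with LRT
above peak − 2·4.60517; one contiguous exceedance region yields one
interval around its highest peak; boundaries are reported at window
midpoints without interpolation.

## Homozygosity mapping and the common haplotype

A run is a maximal stretch of SNPs at which every case is homozygous for
one identical allele; its score is Σ −log10(max(f_i, ε)) over the run,
with f_i the control frequency of the shared allele and
ε = 1/(2 n_controls + 2).  The exact scoring of the published
case–control autozygosity procedure is not reproduced in print; this
score preserves its intent (longer and rarer shared homozygosity ranks
higher) and is the package's documented stand-in.  Phenocopy diagnostics
rank case animals by the number of mismatches they contribute inside the
best candidate segment found when up to k animals may be ignored, with
the leave-one-out gain in top run score as tie-breaker; a single-round
leave-one-out alone cannot separate two or more phenocopies, because
removing one still leaves the segment broken by the others.

The common disease haplotype grows outward from the SNP nearest an
anchor position while all affected animals remain homozygous for one
identical allele sequence and every carrier retains at least one
matching haplotype (`--exact-one-copy` tightens this to exactly one).
One match state is threaded through both directions so a carrier
haplotype must match the whole interval.  Because identity by state
extends past identity-by-descent boundaries with probability roughly the
shared-allele frequency per marker, the extracted interval overhangs the
descent-truth interval by a geometric number of markers at each end;
tests allow a few markers of overhang.

## Variant concordance and monitoring

Concordance filtering restricts to the candidate region first and then
keeps variants at which every known carrier is heterozygous and every
other genotyped animal is homozygous reference.  Missing non-carrier
genotypes are violations under `strict` and compatible (but counted)
under `lenient`; a missing carrier genotype excludes the variant in both
modes, since the carrier condition is then unverifiable.  Near-misses
(at most two violating animals by default) are reported for review.
Allele frequencies per stratum are (n_het + 2 n_hom_alt)/(2 n), computed
in exact rational arithmetic before rounding to two decimals in percent;
the carrier-mating risk under Hardy–Weinberg is (2q(1−q))²/4 — the full
carrier frequency 2q(1−q) rather than the 2q approximation, though both
agree to the printed precision at the frequencies involved.

## The simulator and what passing tests mean

Founder haplotypes draw per-SNP allele frequencies from Uniform(0.05,
0.95) with independent loci; all LD and relatedness arise from gene
dropping through the pedigree with Poisson crossovers on a uniform map
(Haldane, default 1 cM/Mb; genetic position = bp × cM-per-Mb / 100).
The deleterious allele is placed on one founder haplotype and maintained
through six generations by breeding a fixed share (15 %) of each
generation as carrier offspring — a popular-sire dynasty.  Two optional
realism knobs are off by default because they measurably blur
localisation (see the limitations below): `mix_carrier_kinship` lets
carrier parents contribute their non-disease-bearing gametes to random
matings, spreading carrier kinship into the control pool, and
`clinical_affected_fraction` gives a share of true affecteds
clinical-only records with interpolated phenotype codes.  The study
sample (default 40 affected, 31 carriers, 86 free, plus 3 phenocopies
drawn from mutation-free animals and labelled clinically affected) is
drawn from the final generation with exact composition, using rejection
sampling of gametes for the engineered matings.  Background variants in
the synthetic variant table are never left private to the mutant founder
branch: a standing variant carried by the ancestral haplotype is always
co-planted on a mutation-free haplotype present among the genotyped
controls, reproducing the effect of the deep control panels that make
carrier-concordance filtering so specific in practice.  Per-locus
founder-segment labels give exact IBD
truth, including the true shared disease-haplotype interval (the
intersection of mutant founder segments across all disease haplotypes,
clamped to include the locus).  Genotype entries are masked at random
(default 1 %) for QC exercises while phased truth haplotypes are kept.

Features of real data deliberately not emulated: coalescent depth of
background LD (founders are in linkage equilibrium), genotyping error,
non-uniform recombination maps, sequencing error in the variant table,
and genome-wide (multi-chromosome) relationship estimation — the UAR is
built from the one simulated chromosome, which makes its principal
components more collinear with disease status than a genome-wide
relationship matrix would be.  Passing tests therefore demonstrate the
correctness and calibration of the statistical machinery, not that the
simulator is a faithful surrogate for array data of a real breed.

A known consequence, documented deliberately: with a recessive phenotype
that is an almost deterministic function of the locus genotype and
~160 animals, the likelihood surface at well-fitting windows runs into
the σ_e → 0 boundary, the LRT profile across adjacent windows is ragged
(tens of LRT units between neighbouring midpoints), and the 2-LOD rule
then yields support intervals of only a few windows that frequently
miss the exact planted position even though the peak sits on the shared
haplotype.  The acceptance suite measures localisation and coverage
rates as they are; the corresponding test expectations (≥ 90 % argmax
localisation, ≥ 80 % coverage over 20 seeds) are not met by the default
closed-form IBD estimator at this scale, and the suite reports that
honestly rather than loosening the check.

## Numerical choices

Golden-section refinement works on log γ; the boundary γ = 0 is always
compared.  Degenerate designs raise (singular X, zero residual
variance).  The trio-phasing utility resolves heterozygotes by Mendelian
transmission where a homozygous parent forces the phase, then by greedy
agreement with the most frequent compatible local haplotype in a 10-SNP
window (ties resolve to the reference allele), then imputes remaining
missing alleles to the major allele; it is a convenience tool — the
pipeline contract is externally phased input.  All randomness flows from
a single integer seed through independent sub-streams
(`numpy.random.SeedSequence`), making every artifact bit-reproducible.

## Problem sizes

Default test and acceptance runs use 2,000 SNPs on one simulated
120-Mb chromosome, ~160 study animals, 20 simulation seeds for recovery
rates, 2,000 window-permutations for null calibration, and ≤ 12-animal
instances for brute-force oracle comparisons.
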
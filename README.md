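# cldla

Variance-component fine-mapping of recessive disease loci in livestock
from phased SNP haplotypes: combined linkage-disequilibrium and linkage
analysis (cLDLA), case–control homozygosity mapping, common disease
haplotype extraction, carrier-concordance filtering of sequence variants,
and population monitoring of a candidate causal allele.  A gene-dropping
simulator with exact identity-by-descent bookkeeping provides fully
synthetic, truth-annotated study data, so the entire pipeline is testable
without any external dataset.

## Who this is for

Animal geneticists mapping a monogenic recessive defect (the motivating
case is a progressive neurodegenerative syndrome in a dairy cattle breed)
with a study panel of SNP-array genotypes on affected animals,
progeny-confirmed carriers and disease-free herd mates, plus
whole-genome-sequence genotypes on a carrier/control panel for candidate
variant filtering.

## The model

Diagnostic records are encoded as a quantitative phenotype
(free = 1.0, progeny-confirmed carrier = 2.0, pathologically confirmed
affected = 3.0, clinically-confirmed-only animals interpolated at
2.0–2.75 by pedigree evidence) and analysed under the mixed linear model

    y = X β + Z q + e,     q ~ N(0, D_p σ_q²),     e ~ N(0, I σ_e²)

where **X** carries the overall mean and the leading principal components
of the genome-wide unified additive relationship (UAR) matrix (absorbing
population stratification), and **D**_p is the diplotype relationship
matrix at the tested position p, built from locus-IBD probabilities of
all haplotype pairs at the midpoint of a 40-SNP sliding window.  Each
window is tested with the restricted-likelihood ratio

    LRT = -2 [ log L(H0) - log L(H1) ]

against the no-QTL null, referred to a χ²(1 df) threshold with Bonferroni
correction, and peaks are localised with 2-LOD drop-off support intervals
(1 LOD = 2 ln 10 ≈ 4.605 LRT units).

Locus-IBD for a haplotype pair is a two-hypothesis closed form combining
a coalescent prior φ = 1 − (1 − 1/(2Ne))^T, a recombination survival term
exp(−2 T d) over the flanking identity-by-state runs, and the probability
of chance IBS (product of marker homozygosities); see `docs/methods.md`.

Complementary modules perform homozygosity mapping (scored case
homozygosity runs against control allele frequencies, with leave-one-out
diagnostics that flag phenocopies), extraction of the common disease
haplotype (homozygous in all affecteds, at least one copy in every
carrier), concordance filtering of region variants (carriers
heterozygous, everyone else homozygous reference), and allele-frequency /
carrier-mating-risk computations for ongoing population monitoring.

## Worked example

```python
from cldla import SimConfig, simulate_population, significance_threshold
from cldla.cli import analyze_simulation

sim = simulate_population(SimConfig(seed=2))       # 160-animal study
res = analyze_simulation(sim, seed=2)              # qc -> pcs -> scan -> ci
peak_bp, peak_lrt = res["scan"].peak()
ci = res["cis"][0]
print(f"threshold {res['threshold']:.3f}")
print(f"peak LRT {peak_lrt:.1f} at {peak_bp:,} bp")
print(f"2-LOD support interval [{ci.lower_bp:,}, {ci.upper_bp:,}]")
print(f"true shared haplotype {sim.shared_interval_bp}")
```

prints (machine-generated data, seed 2):

```
threshold 25.186
peak LRT 34.5 at 59,931,338 bp
2-LOD support interval [59,298,691, 60,070,890]
true shared haplotype (59243890, 60113544)
```

i.e. the scan clears the Bonferroni χ²(1) threshold (25.2 for ~1917
windows at a 0.001 family-wise level), its maximum falls inside the
interval over which the simulated disease haplotype is shared identically
by descent, and the support interval covers the planted locus at 60 Mb.
Localisation is not always this clean — the acceptance study measures
how often it is (see `docs/methods.md` for an analysis of when and why
the 2-LOD interval misses on this class of simulated data).

Monitoring computations work directly from genotype counts:

```python
from cldla import allele_frequency, mating_risk
rep = allele_frequency([("2013", 122, 2, 0), ("2014", 834, 3, 0),
                        ("2015", 1378, 7, 0)])
print(rep[["stratum", "allele_freq_percent"]].to_string(index=False))
q = 12 / 4668
print("carrier-mating risk: %.7f" % mating_risk(q)[1])
```

```
stratum  allele_freq_percent
   2013                 0.82
   2014                 0.18
   2015                 0.25
 pooled                 0.26
carrier-mating risk: 0.0000066
```

A command-line interface mirrors the library
(`cldla simulate|qc|relmat|scan|ci|homozygosity|haplotype|variants|monitor|run`);
`cldla run --config cfg.yaml --out DIR` executes the full pipeline and
writes a manifest with checksums, seed and per-stage runtimes.

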
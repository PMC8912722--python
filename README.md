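# parapop

Introgression and demographic inference for parapatric species pairs from
multilocus microsatellite (SSR) genotypes.

`parapop` is a library (plus a thin `parapop` command-line wrapper) for the
analysis pipeline common to two-species hybridization studies of the kind run
on the two Taiwanese snakebark maples (*Acer caudatifolium* and
*A. morrisonense*): starting from diploid SSR genotypes across populations of
two parapatric species, it asks whether the genetic admixture between them
reflects recent introgression rather than shared ancestral polymorphism, and
how gene flow reshaped each species's effective population size.

## What it computes

- **Diversity and differentiation** (`parapop.sumstats`): observed and
  expected heterozygosity (*Ho*, *He* = 1 − Σp², the GenAlEx convention),
  fixation index *F* = 1 − *Ho*/*He*, private alleles per species and their
  per-population frequency, hierarchical AMOVA on allele-identity distances
  with permutation tests (Φ_CT among species, Φ_SC among populations within
  species, Φ_ST overall), pairwise population F_ST, and OLS regressions of
  private-allele frequency on altitude/longitude/latitude.
- **Bayesian admixture clustering** (`parapop.admixture`): a STRUCTURE-style
  Gibbs sampler for the admixture model (latent allele-copy assignments Z,
  Dirichlet cluster frequencies P, simplex ancestries Q), replicate alignment,
  Evanno ΔK for choosing the number of clusters, and rule-based introgression
  calls on the ancestry of the other species's cluster
  (pure ≤ 0.05 < introgressed ≤ 0.5 < hybrid ≤ 0.9 < misassigned).
- **Coalescent simulation** (`parapop.coalescent`): a two-deme
  continuous-time structured coalescent with piecewise-constant sizes
  (*Ne*_anc; *Ne*_cau/*Ne*_mor in an early and a recent epoch), windowed
  asymmetric migration defining four scenarios — strict isolation (SI),
  ancient migration (AM), secondary contact (SC), continuous migration (CM) —
  and strict stepwise mutation (±1 repeat) for microsatellites; plus a
  fixed-order summary-statistic vector.
- **Approximate Bayesian computation** (`parapop.abc`): prior sampling,
  reference-table simulation, rejection on standardized Euclidean distance,
  model posterior probabilities and Bayes factors (retained-set frequencies
  or weighted multinomial logistic regression), a marginal-density
  goodness-of-fit test, and Epanechnikov-weighted, local-linear
  regression-adjusted posterior summaries (mode, weighted 2.5/97.5
  percentiles).
- **Decline contrast** (`parapop.demography`): the amplitude of population
  decline r = *Ne*_t1/*Ne*_t2 per species and scenario, compared between
  with- and without-gene-flow scenarios by a Mann–Whitney rank test.
- **Synthetic data** (`parapop.synth`): a calibrated frequency-model
  generator that reproduces the statistical structure of such a study
  (two species, ≈20 + 19 populations, 17 loci, Φ_CT ≈ 0.48, a minority of
  introgressed individuals, altitude-enriched private alleles) with a truth
  table, so every stage is testable without downloads.

## Worked example

`examples/` holds one short script per capability. For instance,

```
python examples/01_diversity_and_differentiation.py
```

generates a 240-individual, 17-locus two-species study and prints

```
per-species diversity (mean over loci +/- SE):
         Ho_mean  Ho_se  He_mean  He_se  F_mean  private_alleles  n_alleles
species
cau        0.350  0.031    0.391  0.036   0.094               30         82
mor        0.291  0.040    0.351  0.047   0.158               32         84

Phi: {'Phi_CT': 0.449, 'Phi_SC': 0.163, 'Phi_ST': 0.539}
permutation p-values: {'Phi_CT': 0.001, 'Phi_SC': 0.001, 'Phi_ST': 0.001}

private-allele frequency vs geography in cau:
            slope       t       p
altitude   0.0000  7.7939  0.0002
```

*Ho* below *He* (positive *F*) reflects within-population structure; Φ_CT is
the fraction of allele-copy variance between species (the generator targets
0.48); the positive altitude slope reproduces the private-allele enrichment
built into the first species's high-elevation populations.
`examples/02_admixture_introgression.py` recovers ancestry with mean
|Q̂ − Q| ≈ 0.03 and picks K = 2 by ΔK; `examples/03_abc_model_selection.py`
rejects strict isolation (Bayes factor > 10³ against SI) for data generated
under secondary contact; `examples/04_decline_contrast.py` contrasts the
decline ratio between SC and SI fits.

The same stages run from the shell:

```
parapop synth --template study --seed 1 --out study
parapop stats --input study.gen --meta study_meta.csv --perms 999 --seed 1 --out stats.json
parapop admixture --input study.gen --meta study_meta.csv --k 2 --chain 2000 --seed 1
parapop pipeline --config run.yaml
```

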
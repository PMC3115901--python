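# epinet

Subpopulation-resolved epistasis analysis of blood pressure.

Essential hypertension is polygenic: blood-pressure regulation is set by
networks of interacting genes, and single-SNP association scans on a
dichotomized endpoint capture almost none of that signal.  `epinet`
implements a two-step alternative for candidate-gene panels (here, the
enzymes of the ceramide/sphingosine-1-phosphate rheostat):

1. **Resolve cohort heterogeneity.**  The density of the indicator
   traits *y* (diastolic and systolic pressure) given covariates *z*
   (metabolic, inflammatory and vascular measures) is modelled as a
   covariate-gated finite mixture

   *f*(**y**|**z**) = Σₖ πₖ(**z**) *f*(**y**|*x*=*k*, **z**),

   with Gaussian class densities and multinomial-logit gating, fitted by
   EM.  The class count is chosen by the sample-size-adjusted BIC,
   −2ℓ + d·ln((n+2)/24), with an entropy tie-break; subjects go to their
   modal class, yielding physiologically homogeneous subpopulations.

2. **Decompose genetic variance within each subpopulation.**  For every
   SNP pair the trait is regressed on the orthogonal Cockerham
   contrasts — additive w_A ∈ {−2p, q−p, 2q} and dominance
   w_D ∈ {−p², pq, −q²} per locus, plus their four products — giving
   variance components V_A, V_D, V_AA, V_AD, V_DA, V_DD that sum to the
   explained variance under Hardy–Weinberg equilibrium.  Epistasis is
   tested by the joint 4-df F-test of the interaction block against a
   Bonferroni threshold α* = α/(n_pairs·n_subpops·n_traits); single-SNP
   heritability is (V_A+V_D)/V_P.  QC (allele frequencies,
   monomorphism, the exact conditional HWE test, two-locus EM linkage
   disequilibrium) is re-evaluated inside every stratum.

Significant inter-genic pairs are collapsed to gene–gene networks whose
edge weights are relative epistatic variances; the package computes six
centrality indices (closeness, betweenness, stress, centroid value,
Katz, closeness vitality), merges per-stratum networks, and subtracts a
known metabolic core network to expose the superimposed regulatory
links.  A synthetic-cohort generator with planted effects provides
ground truth for every stage (the original cohort data are not public).

## Worked example

```python
import epinet as ep

sc = ep.monica_like(K_true=4, n_subjects=2523, seed=1)   # reference scenario
G, pheno, truth = ep.simulate_population(sc)
cfg = ep.RunConfig(geno_path="", panel_path="", pheno_path="",
                   indicators=["diastolic", "systolic"],
                   covariates=sc.covariate_names, k_range=[3, 4, 5],
                   traits=["diastolic", "systolic"], n_restarts=3,
                   seed=1, out_dir="run1")
rep = ep.run_pipeline(cfg, G=G, pheno=pheno)
print(rep.selection_table[["K", "abic", "entropy", "selected"]])
```

prints the class-count sweep

```
 K      abic  entropy  selected
 3 38353.487    0.985     False
 4 37040.711    0.992      True
 5 37089.022    0.972     False
```

— the adjusted BIC recovers the four planted subpopulations with a
near-crisp partition (entropy 0.99).  The per-stratum summary

```
 subpopulation  n_subjects  diastolic_mean  hypertensive_fraction
             0        1071           68.03                   0.00
             3         353          112.17                   1.00
```

shows the top stratum is fully hypertensive, and the diastolic scan
there finds exactly one Bonferroni-significant interaction
(α* = 6.3×10⁻⁶) out of 990 candidate pairs:

```
 subpopulation  n_possible  n_significant  rel_var_max
             3         990              1     0.546192
```

the planted SPTLC3×CERS4 additive-additive effect, whose estimated
relative epistatic variance 0.55 matches its planted value 0.5 —
roughly half the stratum's phenotypic variance carried by one gene-gene
interaction, invisible to a whole-population single-SNP scan.  The
merged gene network then contains that single SPTLC3–CERS4 edge, and
`ep.centrality_indices(rep.merged)` ranks those two genes first.

The same stages are scriptable from the shell:

```sh
epinet simulate --seed 1 --out cohort/
epinet report --config run.yaml --seed 1
```

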
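# tarms

**Tetra-primer ARMS PCR assay design, in-silico validation, gel genotype
calling and diagnostic-test evaluation.**

`tarms` is for molecular diagnostics labs that genotype biallelic SNPs on
agarose gels. A tetra-primer ARMS (T-ARMS) assay genotypes a SNP in a
single PCR: outer primers OF/OR amplify a control product spanning the SNP,
and two allele-specific inner primers (IF, IR) whose 3′ termini sit exactly
on the SNP — each extending only on its own allele — produce two products
of different sizes, so a lane's band pattern reads out the genotype
directly. The toolkit:

* designs the four primers, either under the classical inner-primer rules
  (deliberate second mismatch at −2, strength-paired with the 3′ allele
  mismatch: strong↔weak, medium↔medium) or under a **Tm-matched** strategy
  that searches offsets −2..−4 and all substitutions to bring every
  amplicon-forming primer pair within a Tm budget (default ≤ 2 °C);
* estimates primer Tm by unified nearest-neighbor thermodynamics with the
  Owczarzy Na⁺ correction (0.25 µM oligo, 50 mM Na⁺ defaults);
* predicts per-genotype band patterns by in-silico PCR (exact 3′-terminal
  match gates extension — the ARMS premise) and simulates restriction
  digests for PIRA-style confirmation assays;
* calls genotypes from observed band sizes with agarose-realistic
  tolerances and summarizes cohorts (carrier prevalence);
* evaluates the assay against a reference test: conventional Se/Sp/PPV/NPV
  with exact Clopper-Pearson intervals, and a Hui-Walter Bayesian latent
  class model (`HuiWalterModel(...).fit()`, statsmodels-style) that treats
  both tests as imperfect, fitted by a conjugate Gibbs sampler with
  Gelman-Rubin convergence and posterior-predictive model checks.

The packaged worked example is the bovine CVM assay: SNP rs438228855 (G>T,
V180F) in SLC35A3, the recessive lethal complex-vertebral-malformation
locus of Holstein-derived cattle. See `docs/methods.md` for the model and
its assumptions.

## Worked example

```python
from tarms import cvm, predict_band_pattern, call_genotype, GelObservation

# The published CVM assay (Tm-matched primer set) on the packaged synthetic
# reconstruction of the target region, audited with its published Tm values:
assay = cvm.cvm_assay("modified", use_published_tm=True)
print(assay.product_sizes)
print(assay.constraint_report.pairwise_tm_diffs)

for genotype in ("wild", "carrier", "mutant"):
    print(genotype, sorted(predict_band_pattern(assay, genotype).sizes, reverse=True))

print(call_genotype(GelObservation("bull-17", (392.0, 243.0, 201.0)), assay).call)
```

prints

```
{'OF/OR': 389, 'OF/IR': 199, 'IF/OR': 240}
{'OF/OR': 0.5, 'IF/OR': 2.0, 'OF/IR': 1.7}
wild [389, 199]
carrier [389, 240, 199]
mutant [389, 240]
carrier
```

The control product is 389 bp on both alleles; the wild-specific OF/IR
product is 199 bp; the mutant-specific IF/OR product is 240 bp for this
27-nt inner primer (241 bp for the classical 28-mer set — the two are
indistinguishable on a gel). Every amplicon-forming primer pair is within
the 2 °C Tm budget, which is the constraint this design strategy exists to
satisfy. A lane at ~392/243/201 bp reads as a carrier: all three bands
match within the max(10 bp, 5%) sizing tolerance.

Evaluating the assay against a reference test on a fully concordant 2×2
table (2 carriers, 198 non-carriers):

```python
from tarms import CrossTab, conventional_metrics, HuiWalterModel, LatentClassPrior

ct = CrossTab(2, 0, 0, 198)
print({k: m.pct for k, m in conventional_metrics(ct).items()})

res = HuiWalterModel(ct, LatentClassPrior()).fit(
    chains=2, iterations=20_000, burn_in=5_000, seed=20210522,
    constrain_accuracy=True,   # keep chains out of the mirror mode
)
print(res.summary().round(3).loc[["pi", "se1", "sp1", "ppv1", "npv1"]])
```

prints

```
{'sensitivity': 100.0, 'specificity': 100.0, 'ppv': 100.0, 'npv': 100.0}
           median  ci2.5  ci97.5  rhat
parameter
pi          0.014  0.003   0.039   1.0
se1         0.821  0.350   0.993   1.0
sp1         0.997  0.982   1.000   1.0
ppv1        0.757  0.229   0.990   1.0
npv1        0.998  0.984   1.000   1.0
```

Conventionally (reference taken as gold standard) the concordant table
gives 100% across the board. The latent class model, which lets both tests
be imperfect, is more conservative: with only two positive animals the
sensitivity posterior is wide (35–99%), while specificity and NPV are
pinned near 1 by the 198 concordant negatives — the characteristic shape of
imperfect-gold-standard evaluation at low prevalence.

## Command line

```sh
tarms design   --fasta locus.fa --snp-pos 300 --wild G --mutant T --id rs438228855
tarms check    --assay assay.json
tarms insilico --assay assay.json
tarms digest   --fasta product.fa --site ATGCAT --cut-offset 5
tarms call     --assay assay.json --bands bands.tsv
tarms evaluate --crosstab ct.csv --bayes --seed 42
tarms simulate locus|gel|crosstab ...
```

Exit codes: 0 success, 1 validation error, 2 usage error.

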
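# Methods

`tarms` designs and validates tetra-primer ARMS (T-ARMS) PCR genotyping
assays for biallelic SNPs, predicts their gel readouts in silico, calls
genotypes from observed band sizes, and evaluates a genotyping test against
a reference test both conventionally and with a Bayesian latent class model.
Its canonical worked example is the bovine CVM assay: the G>T missense SNP
rs438228855 in SLC35A3, genotyped by four primers in a single tube.

## The T-ARMS model

Four primers act in one reaction: outer forward/reverse (OF/OR) amplify a
control product spanning the SNP; two inner primers anchor their 3' termini
exactly on the SNP, one per allele and one per strand, so that each extends
only on its own allele (the amplification-refractory principle). Because the
inner primers sit asymmetrically between the outer primers, the two
allele-specific products have different sizes and all three bands are
resolvable on agarose. All coordinates in the package are 1-based inclusive
plus-strand positions, and product sizes follow

    size(OF/OR) = OR5' − OF5' + 1
    size(OF/IR) = IR5' − OF5' + 1
    size(IF/OR) = OR5' − IF5' + 1,

which imply the bookkeeping identity
`size(OF/IR) + size(IF/OR) = size(OF/OR) + (IR5' − IF5' + 1)`.

Each inner primer carries one deliberate mismatch near its 3' end.
Mismatch strength follows the ARMS hierarchy — strong (G/A, C/T), weak
(C/A, G/T), medium (identical bases) — classified on the annealed strand;
the classification is invariant to which strand is chosen because
complementing both members of a pair preserves the class. Two construction
strategies are implemented:

* **ye2001** (classical): the deliberate mismatch sits at offset −2 from the
  3' end and must complement the 3' allele mismatch in strength
  (strong↔weak, medium↔medium).
* **tm_matched**: offsets −2..−4 and all three substitutions are searched
  and candidates ranked by |Tm − Tm(counter outer primer)|, keeping those
  within the Tm budget when any qualify. This strategy may deliberately
  break the classical pairing; the CVM assay that motivates the package does
  exactly that (its inner primers end up with strong+strong and
  strong+medium pairings at offset −4).

The central design constraint is the Tm budget: among the three
amplicon-forming pairs (OF/OR, IF/OR, OF/IR), the largest pairwise Tm
difference must not exceed a threshold, default 2.0 °C, compared with ≤.
The offset window {−2, −3, −4} is searched rather than fixed because
published assays place the second mismatch at any of these positions; the
chosen offset is recorded in the primer's report.

## Melting temperatures

Tm is computed for the oligo against its perfect complement — the convention
under which a single Tm per primer is meaningful even though ARMS primers
deliberately mismatch their template — using the unified nearest-neighbor
ΔH/ΔS parameters with the Owczarzy quadratic ln[Na+] correction applied in
reciprocal-temperature space (via Biopython's `Tm_NN`). Defaults are the
common web-calculator conditions: 0.25 µM oligo (excess single strand),
50 mM Na+, 0 mM Mg2+; all configurable on the `Oligo`. Under these settings
the six published CVM primer Tm values are reproduced within 0.8 °C. The
test suite carries an independent hand-summed nearest-neighbor oracle (its
own constant table and formulas) that must agree with the engine to 0.1 °C.

Note the absolute offset of a few tenths of a degree against the original
web calculator means the engine's own Tm table for the Tm-matched CVM set
shows a 2.7 °C worst pair, while the published Tm table shows exactly
2.0 °C; constraint audits of published assays should therefore supply the
published Tm values (`validate_constraints(..., tm_table=...)`), which is
how the package reproduces the published ΔTm column exactly.

## The synthetic CVM locus and the 240/241 bp discrepancy

The package runs fully offline, so the CVM target region is a SYNTHETIC
reconstruction (`cvm.cvm_locus`): every base covered by a primer footprint
is fixed by the published primer sequences (each deliberate-mismatch
position is recovered from the primer set in which that position is an
exact template match), the SNP alleles are placed at amplicon position 176,
and the remaining bases are seeded random filler. All binding geometry,
product sizes and allele specificity on this locus are exact; only the
filler is arbitrary.

One bookkeeping subtlety is worth stating plainly. With the control product
at 389 bp and the wild-specific product at 199 bp (24-nt inner reverse
primer), the SNP sits 176 bp into the amplicon, and the size identity above
forces the mutant-specific product to 199 subtracted from 389 plus the inner
primers' overlap: 241 bp for the 28-nt classical inner forward primer and
240 bp for the 27-nt Tm-matched one. The published figures round both to
241 (their Tm values confirm the 27-mer is the primer actually used in the
Tm-matched set). The package reports the coordinate-exact sizes — 241 for
the classical set, 240 for the Tm-matched set — and a 1 bp difference is of
course invisible on agarose.

## In-silico PCR

Primer binding is modeled as an all-or-none idealization of ARMS: a
placement is extensible iff the 3'-terminal window (1 base by default)
matches exactly, with up to 3 internal mismatches tolerated elsewhere (one
deliberate ARMS mismatch plus margin). Every convergent forward/reverse
pair of extensible sites within a maximum product size yields one amplicon
whose ends are the primer sequences. Heterozygotes are the union of
products over the two allele templates; no allele competition or extension
efficiency is modeled, which is exactly the idealization a gel readout
encodes. Restriction digestion is linear-molecule string arithmetic: sites
located on both strands (one scan suffices for palindromes like NsiI's
ATGCAT), overlapping occurrences taken left-to-right greedily, fragment
sizes always summing to the input length.

## Genotype calling

Expected bands are matched greedily, nearest first, each observed band
consumed at most once, within a tolerance of max(10 bp, 5% of the expected
size) — agarose sizing against a 100 bp ladder is no better than ~5%, and
the default is a convention, configurable per call. Control-band absence is
`no_call (control failure)`; control present but both allele bands missing
is `no_call (allele dropout)`; otherwise the presence matrix of the two
inner bands gives wild/carrier/mutant. Extra unmatched bands are reported
but only veto the call in strict mode. Carrier prevalence is
100 × (carriers + mutants) / called samples, reported with numerator and
denominator.

## Diagnostic evaluation

Conventional metrics treat the reference test as a gold standard:
Se, Sp, PPV, NPV with exact Clopper-Pearson 95% intervals
(`statsmodels.proportion_confint(method="beta")`), zero denominators
flagged undefined rather than raised.

The Hui-Walter latent class model drops the gold-standard assumption: one
population, two conditionally independent imperfect tests, five parameters
(prevalence π, Se/Sp per test) generating the four cell probabilities of
the 2×2 table. Fitting is by Gibbs sampling with latent-status
augmentation: each observed cell is split into latent positives/negatives
by a binomial draw from the posterior odds, then π and the four accuracies
are drawn from their conjugate Beta full conditionals. The sampler is
therefore exact by construction, and with both tests' accuracies pinned to
1 its prevalence posterior provably collapses to the closed-form Beta
posterior (a property the test suite checks by total-variation distance on
a 5-bin equal-probability partition; finer partitions would push the
Monte-Carlo noise floor of a 10k-draw sample above the 0.01 bound even for
a perfect sampler).

Because one population with two tests gives only 3 degrees of freedom for 5
parameters, the model is partially identifiable and priors matter. Defaults
are Beta(1,1) on π and Beta(2,1) on each Se/Sp (mild regularization toward
informative tests); an all-uniform prior triggers a prominent warning. An
optional label-switching guard (`constrain_accuracy=True`, off by default)
restricts each test to Se + Sp > 1 by sampling from the truncated full
conditionals. The guard matters in practice for weakly informative tables:
the likelihood is invariant under (π, Se, Sp) → (1−π, 1−Se, 1−Sp), and on a
table with only two positives long chains visit both mirror modes under the
default priors, which inflates R-hat and makes marginal medians
meaningless; with the guard on, both chains stay in the epidemiologically
sensible mode and convergence is clean. The acceptance script enables it
for exactly that reason on the concordant 2/198 table. Defaults: 2 chains, 20,000 iterations, 5,000 burn-in, no
thinning, explicit seed; identical seeds give bit-identical results.

Per retained draw, PPV/NPV are computed from (Se, Sp, π) by Bayes' rule.
Convergence is monitored by the classic Gelman-Rubin potential scale
reduction factor (non-split, so two identical chains give exactly
√((n−1)/n) ≈ 1.0; cross-checked against `arviz.rhat` in the tests). Model
fit is assessed by posterior-predictive mid-p values per cell,
P(replicate > observed) + ½ P(replicate = observed) under multinomial
replicates, which center at 0.5 under perfect fit.

The published Bayesian point estimates for the CVM assay (Se 92.2
(41.0–100.0), Sp 99.9, PPV 93.0, NPV 99.9) came from a web application
whose priors and sampler settings are not reported, so they are treated as
qualitative anchors only: the package's acceptance checks assert the
properties those numbers exhibit — a sensitivity interval wider than 30
percentage points on the concordant low-prevalence table, cell-wise
posterior-predictive p-values near 0.5, clean convergence — plus
simulation-recovery coverage (true parameters inside their 95% intervals in
≥18/20 seeded replicates at n = 5000 with mildly informative priors
centered at truth: Beta(1,19) on π, Beta(18,2)/Beta(99,1)/Beta(19,1)/
Beta(99,1) on the accuracies).

## Synthetic data generators

`fixtures` makes everything testable offline. `synth_locus` draws a random
sequence at a requested GC with the SNP planted centrally (≥150 nt flanks
enforced). `synth_gel_cohort` draws genotypes i.i.d. at the given carrier/
mutant frequencies (defaults 1%/0 — the screening scale of the motivating
study: 2 carriers among 200 head), derives each lane's bands by running the
in-silico reaction (never by lookup), perturbs sizes with Gaussian noise
truncated at ±3 SD, drops bands with a dropout probability and adds
spurious bands with an extras probability. `synth_two_test_data` draws
latent statuses Bernoulli(π) and conditionally independent test results.
What these generators do NOT emulate: band intensities, smearing,
extension through terminal mismatches at low rates, heteroduplex artifacts,
population structure (genotype frequencies are fixed, not Hardy-Weinberg).
Passing tests therefore demonstrate the calling and evaluation logic, not
robustness to gel-image pathology.

One documented seed (20210522) is used across the test suite; the
acceptance script derives all its sub-seeds from its `--seed` argument.

## Numerical and degenerate-input choices

* Tm threshold comparison is ≤ (a budget of exactly 2.0 °C passes).
* Outer-candidate ordering: |ΔTm| ascending, ties by (OF 5', OR 5');
  inner-candidate ordering: |Tm − target| then (length, offset,
  substitution base) — all total and deterministic.
* Assay ranking: (violation count ↑, max ΔTm ↑, band separation ↓,
  OF 5' position ↑), stable sort.
* Self-complementarity screen: any perfect self-reverse-complement run
  ≥ 8 nt rejects a primer — a deterministic stand-in for dimer ΔG.
* Empty candidate sets raise a "no candidates" error naming the binding
  constraint that pruned everything; a classical-rule dead end suggests the
  tm_matched strategy.
* Digestion never emits zero-length fragments; a siteless sequence returns
  one whole-length fragment.
* Classical-rule non-compliance is reported per inner primer but is not a
  violation: the Tm budget, not the classical pairing, is this tool's
  acceptance constraint.

## Known limitations

* Tm absolute scale differs by up to ~0.8 °C from the IDT-style calculator
  the published Tm values came from; ΔTm audits of published assays should
  supply published Tm values.
* The ARMS extensibility model is binary; real polymerases read through
  terminal mismatches at some rate, so real gels can show faint
  illegitimate bands the simulator never predicts.
* The latent class model covers one population and two tests under
  conditional independence only; correlated tests or multi-population
  designs are out of scope.
* PIRA primer design (restriction-site-introducing primers) is out of
  scope; the package only provides the generic digest operation used to
  check such assays.
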
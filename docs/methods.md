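# Methods

## The problem

Recorded sexes in animal cohorts are wrong surprisingly often — sampling
mix-ups, data entry, phenotyping errors — and a wrong sex silently corrupts
downstream genetics (X-linked association, pedigree checks, imputation).
Array-based QC tools (e.g. plink's `--check-sex`) detect this from
X-chromosome heterozygosity, but genotyping-by-sequencing (GBS) cohorts pose
two extra problems: genotypes are extremely sparse and shallow (mean depths
well below 3 reads per site), and at low depth a true heterozygote is
routinely miscalled homozygous, which deflates naive heterozygosity in a
depth-dependent way. `gbsex` implements a sex-assignment procedure designed
for exactly this regime, combining a depth-adjusted X heterozygosity with a
Y-chromosome read-presence statistic.

## Model and statistics

Genotypes are called naively from per-site allele depths: any site where
both alleles are observed is heterozygous, a site with reads for one allele
only is homozygous, a site with no reads is missing. Under this caller, a
true heterozygote with read depth `d` is miscalled homozygous exactly when
all `d` reads carry the same allele, which (with reads drawn independently
and evenly from the two alleles) happens with probability `2K`, where
`K = (1/2)^d`. The heterozygote is therefore *detected* with probability
`1 − 2K = 1 − (1/2)^(d−1)`.

For sample `i` over the kept X SNPs `j = 1..M_x`:

    H_i = n_i / Σ_j (1 − 2 K_ij),    K_ij = (1/2)^(d_ij)

where `n_i` is the number of heterozygous calls and the sum runs over SNPs
with `d_ij ≥ 1`. Dividing by the summed detection probabilities makes `H_i`
an (approximately) unbiased estimate of the proportion of truly
heterozygous sites, down to sub-1× depth. Two consequences worth noting:

* depth-1 sites have weight 0 — they carry no heterozygosity information —
  so a sample whose depths are all ≤ 1 has an undefined `H` and is reported
  unusable (`zero_denominator`) rather than assigned;
* `H` can exceed 1 under noise, since the denominator is an expectation,
  not a bound.

The Y statistic is simply `P_Yi`, the proportion of kept Y SNPs with at
least one read in sample `i`: near zero for females (only mis-alignment or
contamination puts Y reads in a female), and roughly `1 − exp(−λ_i)` for
males at mean depth `λ_i`.

The denominator sum is taken over SNPs with `d ≥ 1` rather than all `M_x`
SNPs: including depth-0 sites with `K = 1` would contribute `−1` per
missing site, which has no detection-probability interpretation. The
per-sample statistics table records `n_het`, `denom` and `m_x_used` so the
convention is auditable in every output.

## Classification

A sample is called male if `P_Y > 20·H² + 0.2`, female if `P_Y < 0.1 + H`,
and otherwise unassigned; boundary points (equalities) are unassigned. The
coefficients are the published operating point, fixed empirically on a deer
training cohort; with these defaults the two regions are provably disjoint
for every `H ≥ 0` (the gap polynomial `20H² − H + 0.1` has negative
discriminant), and `DecisionBoundaries` re-checks disjointness in closed
form for any custom coefficients. No boundary refitting is provided: the
original coefficients were chosen by inspection and no fitting procedure
exists to reproduce.

Evaluation follows the field's two conventions separately: *concordance*
(predicted vs recorded sex, unassigned counting as discordant) and
accuracy / sensitivity (true female → predicted female) / specificity
(true male → predicted male) computed among assigned samples only, with
unassigned counts reported alongside.

## SNP filtering

Sex-linked SNP panels from alignment contain mis-mapped and
pseudo-autosomal loci. Using a training cohort with recorded sexes:

| rule | chromosome | threshold | reason code |
|---|---|---|---|
| position in PAR (≥ `par_start_bp`) | X | 170 Mb default | `par` |
| heterozygous males / non-missing males | X | ≥ 10% | `male_het` |
| missing females / all females | X | ≥ 10% | `female_missing` |
| non-missing females / all females | Y | ≥ 5% | `female_nonmissing` |
| heterozygous males / non-missing males | Y | ≥ 50% | `male_het` |
| pooled-read minor allele frequency | both | < 0.015 (strict) | `maf` |

All "at least" rules are inclusive (≥). Design choices the thresholds do
not determine by themselves:

* **Denominators.** Heterozygosity proportions use males with a
  *non-missing call at that SNP*; at mean depth ~1.5 most genotypes are
  missing per SNP, and an all-males denominator would make the 10%/50%
  rules nearly vacuous. Missingness and non-missingness proportions use
  *all* recorded females, because missingness itself is the event measured.
* **MAF from reads, not calls.** At depth ≤ 2 genotype-based allele
  frequencies are badly biased toward homozygotes; pooled read counts are
  not. A SNP with zero total depth has undefined MAF and is discarded with
  reason `maf_undefined`.
* **MAF applies to both X and Y.**
* **Y SNPs are never position-filtered against the PAR**; a Y-assigned tag
  inside the PAR shows reads in females and falls to the 5% rule.
* Rules are evaluated in the order of the table; the filter report
  attributes each discarded SNP to the first rule it triggered (so counts
  are conserved) while recording every triggered rule per SNP.
* A cohort whose mean depth is low enough that typical per-SNP female
  missingness approaches 10% (around 1.5× with moderate sample spread,
  where `E[e^{−λ}] ≈ 0.25`) will lose most X SNPs to the `female_missing`
  rule. That rule is calibrated for training cohorts near 3× depth; on
  shallower data raise `x_female_missing_max` or rely on the positional
  PAR rule alone (see `predict_from_depths(par_start_bp=...)`).

**PAR boundary inference** (`infer_par_boundary`) operationalises the
visual procedure behind the 170 Mb default: per-SNP male heterozygosity is
averaged in non-overlapping 5 Mb windows along the X, and the boundary is
the start of the first window from which every later informative window
exceeds 0.1 mean heterozygosity. Empty windows are ignored; no qualifying
run returns "none found". The inferred value is advisory —
`FilterConfig.par_start_bp` is what the filters use.

**Sample-depth cutoff.** Samples whose mean depth over the kept allosomal
SNPs (zeros included) is below 0.3 are flagged unusable: with only ~16-17 Y
SNPs in a filtered panel, such samples often have no Y reads at all and
males would drift toward unassigned or female. Unusable samples are always
reported with reasons, never dropped.

## Synthetic data

`simulate(SimulationConfig(...))` generates cohorts under the model above:

| parameter | default | meaning |
|---|---|---|
| `n_males`, `n_females` | 200 / 200 | cohort composition |
| `m_x`, `m_y` | 1000 / 16 | panel sizes (post-filter scale of a real panel) |
| `par_start_bp`, `x_length_bp` | 170 Mb / 200 Mb | PAR geometry |
| `par_snp_fraction` | 0.15 | X SNPs placed in the PAR (its length share) |
| `allele_freq_dist` | Beta(2, 2) | X/Y reference-allele frequencies |
| `depth_mean` | 2.89 | mean reads per (sample, site), training-cohort scale |
| `depth_shape` | 20 | Gamma shape for λ_i; `None` = constant λ |
| `per_read_error` | 0.002 | per-read wrong-allele probability |
| `y_leak_rate` | 0.01 | female Y-read Poisson rate per unit λ_i |
| `misassigned_fraction` | 0 | recorded sexes flipped (Bernoulli per sample) |

Females draw two X alleles per SNP (Hardy–Weinberg at the SNP's frequency);
males draw one outside the PAR and two inside; Y loci are haploid male
alleles. Depth is Poisson(λ_i) at every site carried by the sample; female
Y depth is Poisson(`y_leak_rate`·λ_i), so leakage scales with sequencing
effort. Heterozygous sites emit each allele with probability ½ per read,
then each read flips with the error probability. The Gamma shape of 20
(CV ≈ 0.22) represents moderate between-sample depth spread, consistent
with cohorts whose mean depths sit at 1.5-2.9× while samples under the 0.3
cutoff are rare. XXY samples are diploid on the whole X and carry Y; XO
samples are hemizygous X with no Y. Contamination mixes a fraction of a
sample's reads with reads generated from one random donor's genotype at a
stated level — a deliberately simple two-sample mixture, with no claim to
reproduce any particular real contamination signature.

The truth table records true sex, karyotype, the recorded sex after
misassignment flips, the flip indicator, each sample's realized λ_i and its
true heterozygous-site proportion, so estimator recovery can be checked
sample by sample.

What the generator does **not** emulate: linkage disequilibrium between
SNPs, restriction-site dropout (depth is independent across sites given
λ_i), reference bias, batch effects, and genotyping errors that are
systematic rather than per-read. Passing tests therefore demonstrate the
estimator and classifier are correct under the stated sampling model, not
that the published thresholds are optimal for any particular species.

## Validation (what the acceptance script computes)

`scripts/acceptance.py` re-runs, from scratch at a given seed:

1. estimator recovery — 200 diploid samples × 1000 X SNPs at constant
   Poisson depths 0.5×/1×/2×/4×, error 0: the mean `H` is compared with the
   analytic heterozygous-site proportion `2·E[p(1−p)] = 2ab/((a+b)(a+b+1))`
   (= 0.4 for Beta(2,2)); absolute bias is typically < 0.01;
2. decision-region disjointness by dense grid scan (`H` step 1e-4 on [0,2]);
3. the engineered filter fixture (4 X and 3 Y SNPs lost, one per rule);
4. end-to-end recovery — 200 males + 200 females at Gamma-mean 1.5× depth,
   per-read error 0.002, Y leak 0.01: percent of samples assigned their
   true sex (100 in all runs we have executed), plus the same cohort with
   2% misrecorded sexes, where the discordant set should coincide exactly
   with the flipped set;
5. PAR changepoint recovery within one 5 Mb window of the simulated 170 Mb
   boundary.

The end-to-end run applies the deterministic PAR positional rule but not
the cohort-statistic training filters: the simulated panel is clean by
construction, and at 1.5× mean depth the 10% female-missingness rule —
calibrated for ~3× training data — would discard essentially every X SNP
(see the filtering section). Filter behaviour is validated separately on
the engineered fixture. Problem sizes (≤ 200k cells per run) keep the whole
script under a few seconds while leaving Monte-Carlo error an order of
magnitude below the tolerances checked.

## Numerical notes and limitations

* `depth_weight` saturates to 1.0 in float64 beyond depth ≈ 54; harmless,
  since the weight is within 2⁻⁵³ of 1 there.
* `H` for a sample is a ratio estimator; its unbiasedness argument requires
  depth to be independent of genotype at a site, which the simulator
  satisfies and real data approximately satisfies off the PAR.
* The classifier gives no aneuploidy or contamination calls; XXY/XO and
  contaminated samples simply land at atypical (H, P_Y) positions (often
  unassigned), and the simulator can generate them for exploratory plots.
* Chromosome-name normalisation covers common aliases (`X`, `chrX`, `23`,
  …) and accepts an explicit per-contig mapping for anything else.
* With no recorded males or no recorded females the training filters and
  PAR inference are undefined and raise a configuration error rather than
  guessing.
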
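# Methods

## Model and assumptions

`sescore` estimates the causal contribution of each drug-bound receptor to
each reported side-effect by drug-target Mendelian randomization, then
weights that contribution by how strongly the drug engages the receptor.

The causal layer uses one cis-eQTL SNP per (receptor gene, tissue) as an
instrumental variable for receptor expression. The usual IV assumptions
apply: the SNP is robustly associated with expression (relevance, enforced
by the F-statistic gate), is not confounded with the outcome
(independence), and affects the outcome only through expression (exclusion
restriction). With a single instrument neither of the last two can be tested
directly, so the design substitutes a colocalization gate: a locus only
counts if the eQTL and GWAS association signals are consistent with one
shared causal variant (high PP(H4)) and show no evidence of two distinct
variants (low PP(H3)). This guards against LD-induced pleiotropy, the main
failure mode of single-SNP MR, but not against a genuinely pleiotropic
shared variant.

The pharmacological layer assumes the drug's effect on a receptor-mediated
trait is proportional to `beta_IV * (pKi + a_d)`: linear in the causal
effect of expression, linear in log binding affinity, with a multiplicative
dose correction `a_d = pKi * log10(de)` that vanishes at the reference dose
(`de = 1`). Antagonism and inverse agonism flip the sign (blocking the
receptor mimics reduced expression); agonism and positive modulation keep
it. This linear composition is a screening heuristic, not a dose-response
model: scores rank evidence, they are not clinical effect sizes.

## Pipeline and gates

1. **Affinity aggregation.** Per (drug, receptor): discard measurements
   >= `ki_discard_nm`; 10 %-trimmed mean of the survivors; scale with
   `pKi = -log10(Ki_nM * nm_to_m) - 4`. No measurement at all: default
   `pKi = 0.824 (SE 0.15)`. All measurements discarded: the pair is
   *non-binding* and excluded — data showing no engagement is different
   from no data.
2. **Instruments.** Smallest-p SNP within ±1 Mb of the gene interval, per
   tissue; excluded when `F = (beta/se)^2 <= 22`.
3. **Screen.** Wald ratio `beta_IV = beta_ZY / beta_ZX` for every
   (instrument × mapped phenotype) after allele harmonization
   (strand-ambiguous A/T and C/G SNPs are dropped outright — a single
   mis-oriented instrument cannot be detected downstream). Brain-relevant
   phenotypes are screened against brain-tissue instruments, all others
   against blood, per the map's `brain_relevant` flag. One
   Benjamini–Hochberg pass over the entire screen; keep q < 0.05.
4. **Colocalization.** Wakefield ABFs per SNP over the same ±1 Mb window;
   posterior over the five causal configurations; keep PP(H4) >= 0.6 and
   PP(H3) < 0.1.
5. **Selection.** One result per (side-effect, receptor). The library
   function `dedupe_pair_results` uses the chain q-value → larger F →
   smaller SNP id; the fitted pipeline applies colocalization first and
   prefers the tissue with the highest PP(H4) before that chain, so that
   the Wald ratio entering the score is the one whose locus shows the
   strongest evidence of a shared variant.
6. **Scores.** Signed terms, entry sums `S_{d,t}`, drug totals, absolute
   aggregation for cumulative reporting, and the on-/off-target
   classification (a side-effect is on-target-dominated when on- or
   suspected-target receptors contribute > 50 % of its cumulative absolute
   score).

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `f_min` | 22 | — | weak-instrument threshold for a single IV |
| `fdr` | 0.05 | — | screen-wide false discovery rate |
| `h4_min` / `h3_max` | 0.6 / 0.1 | posterior prob. | relaxed H4 bound admits under-powered outcome traits; the H3 bound still rejects loci with distinct-variant evidence. `h4_min` is inclusive (>=) |
| `ki_discard_nm` | 10,000 | nM | binding at or above this is treated as pharmacologically inert |
| `trim` | 0.1 | proportion | removes `floor(0.1·n)` per tail; symmetric trimming is the common convention |
| `default_pki` / `default_pki_se` | 0.824 / 0.15 | pKi | mean over measured pairs, used for bind-but-unmeasured pairs; treated as a configured constant, not recomputed |
| `nm_to_m` | 1e-8 | M/nM | the conversion used by the pKi scaling. It is deliberately not the physical 1e-9: with 1e-8 the discard boundary maps exactly to pKi = 0 and strong binders to ~4.5, which is the scale the score is defined on. Set 1e-9 to use the physical convention (shifts all pKi by −1) |
| `cis_window_bp` | 1,000,000 | bp | cis definition, measured from the gene interval boundaries |
| `coloc_p1, p2, p12` | 1e-4, 1e-4, 1e-5 | per SNP | standard single-variant colocalization priors |
| `prior_sd_quant` / `prior_sd_binary` | 0.15 / 0.2 | effect SD | effect-size priors for quantitative and log-odds outcomes |
| `n_boot` | 1000 | iterations | parametric bootstrap size |

All live in `RunConfig`, round-trip through YAML, and are validated before
any computation.

## Numerical choices

* Colocalization weights are computed in log space; the H3 weight uses an
  explicit off-diagonal log-sum-exp over the `m × m` grid of ordered SNP
  pairs, which is exact (a single-SNP locus gets H3 weight exactly 0) and
  avoids the catastrophic cancellation of the `sum1·sum2 − sum12` form.
  Loci with |z| beyond 60 stay finite.
* The Wald-ratio SE is the first-order delta-method term
  `|se_ZY / beta_ZX|`; `second_order_se=True` adds the exposure-variance
  term. A zero Wald ratio gets p = 1; `beta_ZX = 0` is an error, not a 0/0.
* Bootstrap: `beta_IV ~ N(beta_IV, se_IV)`; measured pairs resample the
  trimmed-mean Ki on the nM scale (truncated at 1e-12 M so the log stays
  defined) and re-scale; default pairs resample pKi ~ N(0.824, 0.15)
  directly, since that is the scale the default is stated on. One affinity
  draw per (drug, receptor) per iteration is shared across all terms of the
  drug, and drug-level SEs are SDs of summed replicates — not sums of SEs —
  so within-drug dependence on common binding estimates is respected.
  `beta_IV` and affinity are resampled independently (no covariance is
  available to model).
* Deduplication and instrument selection break all ties deterministically
  (stable sorts ending at the SNP id), and every stochastic routine takes
  an explicit seed, so identical (config, seed, inputs) produce
  byte-identical outputs.
* Trimmed-mean SE is `sd/sqrt(k)` over the k retained values (0 when
  k = 1); empty measurement lists are an error at the operation level and a
  default-imputation signal at the summary level.

## Direction conventions

Antagonist and inverse agonist → −1; agonist and positive modulator → +1;
inhibitor → −1 (grouped with antagonism: it reduces receptor activity).
Partial agonists and unknown actions get +1 with a logged warning — their
binding relationships are non-linear and no principled sign exists, so
direction-aware views should be read with that caveat; absolute-value
aggregation is unaffected.

## What the synthetic data does and does not emulate

`sescore.simulate` produces summary-statistic-level data: AR(1) LD
(`corr = rho^|i−j|`, default rho = 0.9), marginal effects = LD row × causal
vector, estimation noise with the analytic SE `1/sqrt(2·maf·(1−maf)·n)`
correlated according to the same LD. Default study conditions: causal eQTL
effect `beta_zx = 0.3`, causal expression→trait effect `theta = 0.5`,
n = 50,000 per trait, maf = 0.3, 40-SNP loci, five brain tissues plus
blood. Ki tables draw 3–8 log-normal measurements per pair
(sd 0.15 log10 units), inflate 5 % of them 100–1000× (outliers that the
trimmed mean must absorb), and leave 10 % of pairs unmeasured (exercising
the default-pKi path). A fraction of GWAS rows is stored on the swapped
allele so harmonization is always exercised.

Not emulated: realistic LD panels (block structure, long-range LD),
allele-frequency spectra (one maf per locus), sample overlap between eQTL
and GWAS, population stratification, binary-trait ascertainment, and
between-tissue correlation of eQTL noise (tissues are independent draws
around a shared causal effect, which makes multi-tissue agreement easier
than in real brain data). Passing the recovery benchmark therefore shows
the gate chain is wired correctly and calibrated under ideal assumptions —
not that real catalogues would yield the same power.

## Known limitations

* Single-instrument MR: no heterogeneity or pleiotropy diagnostics (Egger,
  IVW) are possible by construction; the colocalization gate is the only
  pleiotropy control.
* eQTL direction can disagree with protein-level effects; scores inherit
  that uncertainty, which is one reason cumulative reporting uses absolute
  values.
* The default pKi treats all unmeasured binding identically; pairs that in
  truth bind weakly are over-weighted and strong unmeasured binders
  under-weighted.
* Scores rank genetic evidence for side-effect liability; they are not
  calibrated to clinical severity or frequency.
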
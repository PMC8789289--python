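# Methods

This note documents the statistical model behind `adipomr`, the
assumptions and defaults of each stage, what the synthetic-data generator
does and does not emulate, and the design decisions taken where more than
one convention exists.

## Two-sample MR model

Each genetic variant j is an instrument for an adiposity exposure, with
association γ_j ± se_γj (SD of exposure per allele) estimated in one GWAS
and Γ_j ± se_Γj (log-odds of disease per allele) estimated in an
independent GWAS. Under the instrumental-variable assumptions (relevance,
no confounding of the variant–outcome relation, no effect on the outcome
except through the exposure), each Wald ratio Γ_j/γ_j estimates the causal
log-odds per SD, and the estimators combine them:

* **IVW** is the se_Γ^−2-weighted regression of Γ on γ through the
  origin. We use first-order weights: exposure-side uncertainty is
  ignored, the standard convention when instruments are genome-wide
  significant (per-variant |γ/se_γ| ≳ 6, so the second-order correction is
  below ~2%).
* **MR-Egger** frees the intercept, which under the InSIDE assumption
  (pleiotropic effects independent of instrument strength) estimates mean
  directional pleiotropy; its slope is a pleiotropy-adjusted effect.
  Instruments are oriented to positive γ before fitting, without which the
  intercept is not identifiable.
* **Weighted median**: ratios sorted ascending with normalised inverse-
  variance weights w′_j; the estimate linearly interpolates the sorted
  ratios at the 50% point of the cumulative midpoints p_j = S_j − w′_j/2.
  Its SE is the standard deviation over a parametric bootstrap (default
  5000 replicates) that redraws each γ_j and Γ_j from their sampling
  distributions; the bootstrap is seeded and bit-reproducible.

**Variance model.** Cochran's Q is computed from weighted residuals (L−1
df for IVW, L−2 for Egger) with I² = max(0, (Q−df)/Q)·100. By default the
multiplicative random-effects model inflates standard errors by
√max(1, Q/df) when L ≥ 4 and the fixed model is used below that, mirroring
the behaviour of the widely used MR software this package is
interoperable with; either model can be forced. p-values and 95% CIs use
the normal reference (±1.96·se), not a t reference — a declared
convention, defensible at the instrument counts used here (36–696).

**Egger I² diagnostics.** Besides the residual-heterogeneity I² from the
Egger Q, the instrument-strength spread statistic I²_GX (from
Q_GX = Σ se_γj^−2 (γ_j − γ̄_w)²) is available as a separate diagnostic.
Classification uses neither.

## Harmonisation

Variants are keyed by rsID only; no chromosome/position matching and no
LD operations (instrument lists are taken as given). When the outcome
study reports the alleles swapped, Γ is sign-flipped and eaf replaced by
1−eaf; non-palindromic pairs on the opposite strand are
complement-matched automatically. Palindromic (A/T, G/C) variants cannot
be strand-resolved from alleles: the default policy drops them; the
`infer_by_eaf` policy aligns by comparing both allele frequencies to 0.5
and drops the variant when either frequency lies within 0.08 of 0.5 (the
window is configurable) or is missing — alignment is never guessed.
Irreconcilable allele pairs are dropped with reason `allele mismatch`,
never raised. Every variant in the ID intersection ends up exactly once in
either the retained records or the drop log.

## Meta-analysis and the validation arm

Per-source IVW estimates for the same exposure–outcome pair are combined
with the DerSimonian–Laird method-of-moments random-effects model (the
historical default of the standard meta-analysis software for this model
class; REML is out of scope). Outcomes present in only one source pass
through with τ² = 0 and k = 1 recorded. A validation source (a biobank in
which the BFP/FA/UFA instruments were largely discovered) is analysed
identically but flagged non-meta-analysable: it is never combined with the
main sources and never feeds classification, only the directional-
consistency sensitivity counts.

## FDR and classification

Benjamini–Hochberg q-values are computed per exposure across the disease
panel (never pooled across exposures), separately within the meta arm and
the validation arm. The threshold is 0.1, strict (`q < 0.1` counts as
significant; `q` exactly at threshold does not).

Classification is a gated tree over the four meta-arm estimates:

1. BMI q ≥ 0.1 → `no_bmi_effect`.
2. BFP q ≥ 0.1 or sign(BFP) ≠ sign(BMI) → `not_fat_driven` (the BMI
   signal is not carried by fat mass).
3. Otherwise let d = sign of the BMI/BFP effect; FA and UFA betas are
   oriented by d, so globally protective outcomes (d < 0, e.g. the
   postmenopausal-breast-cancer pattern) classify symmetrically and are
   flagged `protective_outcome`. With oriented effects:
   * UFA significant risk-directional, FA significant opposite →
     `metabolic`;
   * UFA and FA both significant risk-directional → `non_metabolic`;
   * UFA significant risk-directional, FA opposite-directional but
     q ≥ 0.1 → `combination_metabolic`;
   * UFA significant risk-directional, FA risk-directional but q ≥ 0.1 →
     `combination_non_metabolic`;
   * anything else → `inconclusive`.

A beta of exactly 0 is non-directional and resolves to `inconclusive`
(deterministic tie-break). The FA-significant/UFA-null pattern returns
`inconclusive` by design: it is suggestive of a metabolic component but
does not meet the two-arm criteria, and a single uniform rule is
preferred over narrative exceptions. p-value-based annotations are
reported but never drive the category.

## Synthetic data generator

The generator emulates the study design, not any particular cohort. Each
variant carries a true adiposity effect γ*_j ~ |Normal(a, 0.012)| with
a = 0.03 SD/allele (typical of genome-wide-significant adiposity loci)
and a metabolic loading m_j: FA variants −m·|Normal(1, 0.25)|, UFA
variants +m·|Normal(1, 0.25)| with m = 0.03, and generic BMI/BFP variants
m·Normal(0.6, 0.4) — a positive-mean mixture, encoding that higher
adiposity is on average metabolically adverse (without which a purely
metabolic disease would show no BMI signal at all, contrary to the
phenomenology the design rests on). A disease's true per-allele effect is

    Γ*_j = θ_mech·γ*_j + θ_met·m_j + e_j

with θ_mech the effect of adiposity per se and θ_met the metabolic-pathway
effect (log-odds per SD; both default to 0.4, odds ratio ≈ 1.5/SD, typical
of the stronger adiposity–disease relations), and e_j optional balanced or
directional pleiotropy. Observed effects add independent normal noise:
exposure estimates are drawn once per exposure GWAS and shared across
outcome sources — as in a real two-sample design with a single exposure
study — while outcome noise is independent per source. Instrument SEs are
calibrated so per-variant z ≈ 6–10; outcome SEs default to ~0.01
log-odds/allele, giving per-arm IVW |z| ≈ 5–6 at the default θ — the
high-power regime in which pathway recovery is assessed. Instrument
counts default to 73 BMI / 696 BFP / 36 FA / 38 UFA with exactly 5
variant IDs shared between BMI and BFP (shared variants get independent,
exposure-trait-specific weight estimates, one shared truth). Disease
outcomes are generated directly on the summary-statistic scale rather
than via individual-level logistic sampling: the pipeline consumes only
summary statistics, and this keeps whole-panel replication fast enough
for Monte-Carlo work on one CPU.

What the generator does **not** emulate: linkage disequilibrium between
instruments, winner's curse in instrument selection, sample overlap
between exposure and outcome GWAS, case–control ascertainment, and
non-collapsibility of the odds ratio. Passing tests therefore demonstrate
that the inference chain is correct under its own assumptions, not that
those assumptions hold in any given real dataset.

## Calibration experiments and problem sizes

`adipomr.calibration` quantifies the chain's behaviour under known truth;
`scripts/acceptance.py` reruns these from scratch. Problem sizes were
chosen to put Monte-Carlo error well below the widths of the bands being
checked while keeping the whole run in the minutes range on one CPU: 2000
replicates for Q-statistic null calibration (MC SE ≈ 0.5% on a 5% rate),
1000 for CI coverage and Egger-intercept recovery, 1000 panels for the
realised-FDR experiment (37 diseases, ~50% true nulls), 500 panels for
classification recovery (10 metabolic-only + 9 mechanical-only + 18 null
diseases per panel — a panel width mirroring the intended study design,
with enough null diseases that a null's q-value sits above its p-value
under BH rather than exactly at it).

## Numerical choices and degenerate inputs

* Two-sided p-values are clamped at the smallest positive normal double;
  extreme z-scores would otherwise underflow to an invalid p = 0.
* A single instrument reduces IVW to the Wald ratio with heterogeneity
  fields absent; Egger and the weighted median require L ≥ 3 and raise
  structured errors below that, which the pipeline logs and skips rather
  than crashes on.
* Egger raises a degenerate-design error when all oriented γ are equal
  (singular design).
* Zero-γ variants are dropped at harmonisation (the ratio is undefined);
  an exactly zero resampled γ in the bootstrap (measure-zero) is guarded.
* Weighted-median bootstrap seeds derive deterministically from the run
  seed and the (exposure, disease, source) triple via crc32, so partial
  re-runs and full re-runs agree byte-for-byte; all TSV output uses a
  fixed float format for the same reason.

## Known limitations

* Only first-order ratio SEs; no MR-PRESSO, mode-based, contamination-
  mixture or multivariable MR; no Steiger filtering; no Hartung–Knapp
  adjustment in the meta-analysis; no REML τ².
* No VCF parsing, liftover, LD clumping or proxy lookup — instrument
  lists and summary tables are taken as given, rsID-keyed.
* The decision tree formalises prose criteria; patterns outside it (e.g.
  one significant arm with the other null) are deliberately
  `inconclusive` rather than adjudicated case by case.
* Disease subtypes are ordinary extra outcomes; no subtype-aware logic.
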
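"""Per-exposure FDR control and causal-component classification.

Across a panel of diseases, each of the four exposures (BMI, body-fat
percentage, favourable adiposity FA, unfavourable adiposity UFA) yields one
meta-analysed MR estimate per disease.  Benjamini-Hochberg q-values are
computed separately per exposure across the panel, and each disease is
assigned a causal-component category from the pattern of the four
estimates:

* ``no_bmi_effect`` -- no evidence that BMI affects the disease at all.
* ``not_fat_driven`` -- the BMI effect is not confirmed by body-fat
  percentage (wrong sign or not significant), so fat mass is unlikely to
  be the driver.
* ``metabolic`` -- UFA raises risk while FA (higher adiposity with a
  favourable metabolic profile) protects: the adverse metabolic
  consequences of adiposity drive the disease.
* ``non_metabolic`` -- FA and UFA both raise risk: adiposity per se (e.g.
  its mechanical load) drives the disease.
* ``combination_metabolic`` / ``combination_non_metabolic`` -- UFA raises
  risk and FA points the corresponding way but misses the FDR threshold.
* ``inconclusive`` -- any other pattern.

Directionality is oriented by the sign of the BMI/BFP effect so that
globally protective outcomes (adiposity lowering disease risk) classify
symmetrically; such outcomes are flagged ``protective_outcome``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CATEGORIES",
    "EXPOSURES",
    "ExposureSummary",
    "DiseaseVerdict",
    "bh_fdr",
    "classify_disease",
]

EXPOSURES = ("bmi", "bfp", "fa", "ufa")

CATEGORIES = (
    "metabolic",
    "non_metabolic",
    "combination_metabolic",
    "combination_non_metabolic",
    "no_bmi_effect",
    "not_fat_driven",
    "inconclusive",
)


@dataclass(frozen=True)
class ExposureSummary:
    """One exposure's meta-analysed estimate for one disease."""

    beta: float
    se: float
    pvalue: float
    qvalue: float


@dataclass
class DiseaseVerdict:
    disease: str
    per_exposure: dict[str, ExposureSummary]
    category: str
    protective_outcome: bool


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order.

    q_i = min over j >= i of (m * p_(j) / j), capped at 1.  Applied per
    exposure across the disease panel; never pooled across exposures.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_disease(
    disease: str,
    per_exposure: Mapping[str, ExposureSummary],
    fdr_threshold: float = 0.1,
) -> DiseaseVerdict:
    """Assign one disease its causal-component category.

    ``per_exposure`` maps exposure names (lower case: ``bmi``, ``bfp``,
    ``fa``, ``ufa``) to their meta-analysed summaries; ``bmi`` is required,
    the others may be absent (classification then stops at the gate it can
    reach).  Significance is strict: q < threshold.  A beta of exactly 0 is
    non-directional and resolves to ``inconclusive``.
    """
    if "bmi" not in per_exposure:
        raise ValueError(f"{disease}: BMI estimate is required")
    summaries = dict(per_exposure)

    def verdict(category: str, protective: bool = False) -> DiseaseVerdict:
        return DiseaseVerdict(
            disease=disease,
            per_exposure=summaries,
            category=category,
            protective_outcome=protective,
        )

    bmi = summaries["bmi"]
    # gate (a): is BMI causal at all?
    if bmi.qvalue >= fdr_threshold:
        return verdict("no_bmi_effect")
    if bmi.beta == 0:
        return verdict("inconclusive")
    d = 1.0 if bmi.beta > 0 else -1.0
    protective = d < 0

    # gate (b): confirm the effect is carried by fat mass
    bfp = summaries.get("bfp")
    if bfp is None:
        return verdict("inconclusive", protective)
    if bfp.qvalue >= fdr_threshold or np.sign(bfp.beta) != np.sign(bmi.beta):
        return verdict("not_fat_driven", protective)

    fa = summaries.get("fa")
    ufa = summaries.get("ufa")
    if fa is None or ufa is None:
        return verdict("inconclusive", protective)

    # orient FA/UFA by the risk direction of the BMI/BFP effect
    fa_o = d * fa.beta
    ufa_o = d * ufa.beta
    fa_sig = fa.qvalue < fdr_threshold
    ufa_sig = ufa.qvalue < fdr_threshold

    if ufa_sig and ufa_o > 0:
        if fa_sig and fa_o < 0:
            return verdict("metabolic", protective)
        if fa_sig and fa_o > 0:
            return verdict("non_metabolic", protective)
        if fa_o < 0:
            return verdict("combination_metabolic", protective)
        if fa_o > 0:
            return verdict("combination_non_metabolic", protective)
    return verdict("inconclusive", protective)
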
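"""Monte-Carlo calibration experiments on the synthetic study design.

These routines quantify the statistical behaviour of the pipeline under
the generator's known ground truth: null calibration of the IVW
heterogeneity statistic, confidence-interval coverage, Egger-intercept
recovery of injected directional pleiotropy, realised false-discovery
proportions under BH at a given threshold, and end-to-end classification
recovery.  They are the package's own evidence that the estimators and the
decision layer behave as advertised before being pointed at real summary
statistics.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import stats

from .classify import bh_fdr
from .estimators import egger, ivw
from .pipeline import classify_synthetic_study
from .simulate import (
    DiseaseSpec,
    SyntheticConfig,
    simulate_instruments,
    simulate_study,
    simulate_two_sample,
)
from .sumstats import HarmonisedDataset

__all__ = [
    "q_null_rejection_rate",
    "ci_coverage",
    "egger_intercept_recovery",
    "fdr_experiment",
    "classification_recovery",
]


def q_null_rejection_rate(
    config: SyntheticConfig,
    theta: float,
    n_reps: int,
    seed: int,
    exposure: str = "fa",
    alpha: float = 0.05,
) -> float:
    """Rejection rate of IVW's Q at the chi-square (1-alpha) quantile under
    exact homogeneity.

    Instruments are drawn once and held fixed; each replicate redraws
    ``Gamma_j = theta*gamma_j + Normal(0, se_Gamma_j)``, the homogeneous
    null of the heterogeneity test.  A calibrated test rejects at rate
    ~alpha.
    """
    panel = simulate_instruments(config, seed)
    obs = panel.observed[exposure]
    gamma = obs["beta"].to_numpy()
    se_gamma = obs["se"].to_numpy()
    L = len(gamma)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    se_G = config.se_Gamma_scale * rng.uniform(0.8, 1.2, L)
    crit = stats.chi2.ppf(1.0 - alpha, L - 1)
    vid = obs["variant_id"].to_numpy()
    hits = 0
    for _ in range(n_reps):
        Gamma = theta * gamma + se_G * rng.standard_normal(L)
        data = HarmonisedDataset(
            exposure_name=exposure,
            outcome_name="null_calibration",
            source_name="sim",
            variant_id=vid,
            gamma=gamma,
            se_gamma=se_gamma,
            Gamma=Gamma,
            se_Gamma=se_G,
        )
        if ivw(data).Q > crit:
            hits += 1
    return hits / n_reps


def ci_coverage(
    config: SyntheticConfig,
    theta_mech: float,
    n_reps: int,
    seed: int,
    exposures: tuple[str, ...] = ("fa", "ufa"),
) -> dict[str, float]:
    """95% CI coverage of the true causal effect for a mechanical-only
    disease (no pleiotropy), per exposure arm.

    Each replicate redraws instruments (exposure-GWAS noise included) and
    one outcome source.
    """
    cfg = replace(config, n_meta_sources=1, include_validation=False)
    spec = DiseaseSpec("mechanical_only", theta_mech=theta_mech)
    covered = {e: 0 for e in exposures}
    for rep in range(n_reps):
        panel = simulate_instruments(cfg, seed + 2 * rep)
        d = simulate_two_sample(cfg, panel, spec, seed=seed + 2 * rep + 1)
        for e in exposures:
            est = ivw(d.harmonised(e, "source_1"))
            if est.ci_low <= theta_mech <= est.ci_high:
                covered[e] += 1
    return {e: covered[e] / n_reps for e in exposures}


def egger_intercept_recovery(
    config: SyntheticConfig,
    n_reps: int,
    seed: int,
    exposure: str = "ufa",
) -> tuple[float, float, float]:
    """Mean Egger intercept under directional pleiotropy.

    Returns ``(mean intercept, Monte-Carlo SE of the mean, injected
    mean)``.  The config must have ``pleiotropy_mode='directional'``; the
    disease is otherwise null so the intercept isolates the injected mean.
    """
    if config.pleiotropy_mode != "directional":
        raise ValueError("config must use pleiotropy_mode='directional'")
    cfg = replace(config, n_meta_sources=1, include_validation=False)
    intercepts = np.empty(n_reps)
    for rep in range(n_reps):
        panel = simulate_instruments(cfg, seed + 2 * rep)
        d = simulate_two_sample(cfg, panel, DiseaseSpec("null"), seed=seed + 2 * rep + 1)
        intercepts[rep] = egger(d.harmonised(exposure, "source_1")).intercept
    mean = float(intercepts.mean())
    mcse = float(intercepts.std(ddof=1) / np.sqrt(n_reps))
    return mean, mcse, config.pleiotropy_mean


def fdr_experiment(
    config: SyntheticConfig,
    n_reps: int,
    seed: int,
    n_causal: int = 18,
    n_null: int = 19,
    threshold: float = 0.1,
    exposure: str = "bmi",
) -> float:
    """Mean realised false-discovery proportion among q < threshold calls.

    Each replicate simulates a disease panel with ``n_causal``
    mechanical-only diseases and ``n_null`` nulls, computes one IVW
    p-value per disease on the given exposure arm, applies BH across the
    panel, and records V/R (0 when nothing is called).
    """
    cfg = replace(config, n_meta_sources=1, include_validation=False)
    fdp = np.empty(n_reps)
    for rep in range(n_reps):
        base = seed + rep * (n_causal + n_null + 1)
        panel = simulate_instruments(cfg, base)
        pvals, is_null = [], []
        for i in range(n_causal + n_null):
            null = i >= n_causal
            spec = DiseaseSpec("null" if null else "mechanical_only")
            d = simulate_two_sample(cfg, panel, spec, seed=base + 1 + i)
            pvals.append(ivw(d.harmonised(exposure, "source_1")).pvalue)
            is_null.append(null)
        q = bh_fdr(pvals)
        called = q < threshold
        R = int(called.sum())
        V = int((called & np.asarray(is_null)).sum())
        fdp[rep] = V / R if R else 0.0
    return float(fdp.mean())


def classification_recovery(
    config: SyntheticConfig,
    n_reps: int,
    seed: int,
    n_metabolic: int = 10,
    n_mechanical: int = 9,
    n_null: int = 18,
    fdr_threshold: float = 0.1,
) -> dict[str, float]:
    """End-to-end category recovery rates on panels with known truth.

    Each replicate simulates a full panel (all four exposure arms, both
    meta sources), runs IVW + meta-analysis + per-exposure BH +
    classification, and scores each disease against its generating kind.
    Returns per-kind recovery rates: metabolic-only panels classified
    ``metabolic``, mechanical-only classified ``non_metabolic``, and null
    diseases gated to ``no_bmi_effect``.
    """
    cfg = replace(config, include_validation=False)
    panel_spec = (
        [(f"met{i}", DiseaseSpec("metabolic_only")) for i in range(n_metabolic)]
        + [(f"mech{i}", DiseaseSpec("mechanical_only")) for i in range(n_mechanical)]
        + [(f"null{i}", DiseaseSpec("null")) for i in range(n_null)]
    )
    hits = {"metabolic": 0, "non_metabolic": 0, "no_bmi_effect": 0}
    totals = {
        "metabolic": n_metabolic * n_reps,
        "non_metabolic": n_mechanical * n_reps,
        "no_bmi_effect": n_null * n_reps,
    }
    for rep in range(n_reps):
        study = simulate_study(cfg, panel_spec, seed=seed + rep)
        verdicts, _ = classify_synthetic_study(study, fdr_threshold=fdr_threshold)
        for name, v in verdicts.items():
            if name.startswith("met") and v.category == "metabolic":
                hits["metabolic"] += 1
            elif name.startswith("mech") and v.category == "non_metabolic":
                hits["non_metabolic"] += 1
            elif name.startswith("null") and v.category == "no_bmi_effect":
                hits["no_bmi_effect"] += 1
    return {k: hits[k] / totals[k] for k in hits}
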
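"""Two-sample MR causal estimators and heterogeneity diagnostics.

All estimators consume a :class:`~adipomr.sumstats.HarmonisedDataset` with
per-variant exposure effects ``gamma`` (SD/allele) and outcome effects
``Gamma`` (log-odds/allele) and return a causal effect on the log-odds per
SD scale.

Implemented methods:

* ``ivw`` -- inverse-variance-weighted estimate, i.e. the weighted
  regression of Gamma on gamma through the origin with weights
  ``se_Gamma**-2`` (first-order weights; exposure uncertainty is ignored).
* ``egger`` -- the same weighted regression with a free intercept; the
  intercept estimates average directional pleiotropy.
* ``weighted_median`` -- the 50% point of the weight-ordered Wald-ratio
  distribution, consistent when valid instruments carry more than half of
  the weight; its SE comes from a seeded parametric bootstrap.

Cochran's Q is reported for IVW (L-1 df) and Egger (L-2 df) together with
the percentage-scale I^2 transform.  Under the ``multiplicative_random``
variance model (the default for L >= 4) standard errors are inflated by
``sqrt(max(1, Q/df))``.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy import stats

from .sumstats import HarmonisedDataset

__all__ = [
    "MREstimate",
    "ratio_estimates",
    "ivw",
    "egger",
    "weighted_median",
    "i2_gx",
    "EstimatorError",
    "EmptyInstrumentError",
    "InsufficientInstrumentsError",
    "DegenerateDesignError",
]

Z_95 = 1.959963984540054  # Phi^-1(0.975)


class EstimatorError(Exception):
    """Base class for estimator errors."""


class EmptyInstrumentError(EstimatorError):
    """No instruments available."""


class InsufficientInstrumentsError(EstimatorError):
    """Too few instruments for the requested method."""


class DegenerateDesignError(EstimatorError):
    """The regression design matrix is singular."""


@dataclass
class MREstimate:
    """One method's causal estimate for one exposure-outcome-source triple.

    ``beta`` is the causal log-odds per SD of exposure.  Heterogeneity
    fields are ``None`` where undefined (single instrument, or the weighted
    median); the Egger intercept fields are ``None`` for other methods.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_variants: int
    Q: float | None = None
    Q_df: int | None = None
    Q_pvalue: float | None = None
    I2: float | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pvalue: float | None = None

    def to_row(self) -> dict:
        """Tidy-row form for TSV export; OR = exp(beta) for reporting."""
        return {
            "method": self.method,
            "n_variants": self.n_variants,
            "beta": self.beta,
            "OR": float(np.exp(self.beta)),
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pvalue": self.pvalue,
            "Q": self.Q,
            "Q_df": self.Q_df,
            "Q_pvalue": self.Q_pvalue,
            "I2": self.I2,
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "intercept_pvalue": self.intercept_pvalue,
        }


def _resolve_variance_model(variance_model: str | None, L: int) -> str:
    if variance_model is None:
        return "multiplicative_random" if L >= 4 else "fixed"
    if variance_model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown variance_model {variance_model!r}")
    return variance_model


def _two_sided_p(z: float) -> float:
    # clamp: extreme z underflows sf to 0, but p-values must stay in (0, 1]
    return float(max(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny))


def ratio_estimates(
    data: HarmonisedDataset,
) -> list[tuple[str, float, float]]:
    """Per-variant Wald ratios Gamma/gamma with first-order delta SEs.

    The first-order SE ``se_Gamma/|gamma|`` ignores exposure uncertainty,
    the dominant convention for genome-wide-significant instruments.
    """
    if np.any(data.gamma == 0):
        raise ValueError("gamma must be nonzero for all retained variants")
    ratio = data.Gamma / data.gamma
    ratio_se = data.se_Gamma / np.abs(data.gamma)
    return list(zip(data.variant_id.tolist(), ratio.tolist(), ratio_se.tolist()))


def ivw(
    data: HarmonisedDataset,
    variance_model: str | None = None,
) -> MREstimate:
    """Inverse-variance-weighted causal estimate.

    beta = sum(w*gamma*Gamma)/sum(w*gamma^2) with w = se_Gamma^-2.  With a
    single instrument this reduces to the Wald ratio and heterogeneity
    fields are absent.
    """
    L = data.n_variants
    if L == 0:
        raise EmptyInstrumentError("IVW requires at least one instrument")
    g, G, sG = data.gamma, data.Gamma, data.se_Gamma
    if L == 1:
        beta = float(G[0] / g[0])
        se = float(sG[0] / abs(g[0]))
        return MREstimate(
            method="wald_ratio",
            beta=beta,
            se=se,
            ci_low=beta - Z_95 * se,
            ci_high=beta + Z_95 * se,
            pvalue=_two_sided_p(beta / se),
            n_variants=1,
        )
    vm = _resolve_variance_model(variance_model, L)
    w = sG**-2.0
    denom = float(np.sum(w * g * g))
    beta = float(np.sum(w * g * G) / denom)
    se = denom**-0.5
    Q = float(np.sum(w * (G - beta * g) ** 2))
    df = L - 1
    if vm == "multiplicative_random":
        se *= max(1.0, Q / df) ** 0.5
    I2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    return MREstimate(
        method="ivw",
        beta=beta,
        se=se,
        ci_low=beta - Z_95 * se,
        ci_high=beta + Z_95 * se,
        pvalue=_two_sided_p(beta / se),
        n_variants=L,
        Q=Q,
        Q_df=df,
        Q_pvalue=float(stats.chi2.sf(Q, df)),
        I2=I2,
    )


def egger(
    data: HarmonisedDataset,
    variance_model: str | None = None,
) -> MREstimate:
    """MR-Egger regression: weighted fit of Gamma = intercept + beta*gamma.

    Instruments are first oriented so every gamma is positive (flipping
    (gamma, Gamma) sign pairs), which makes the intercept identifiable as
    average directional pleiotropy.
    """
    L = data.n_variants
    if L < 3:
        raise InsufficientInstrumentsError("MR-Egger requires at least 3 instruments")
    flip = np.sign(data.gamma)
    g = data.gamma * flip
    G = data.Gamma * flip
    sG = data.se_Gamma
    w = sG**-2.0
    Sw = float(np.sum(w))
    Swx = float(np.sum(w * g))
    Swy = float(np.sum(w * G))
    Swxx = float(np.sum(w * g * g))
    Swxy = float(np.sum(w * g * G))
    D = Sw * Swxx - Swx * Swx
    if D <= 0 or not np.isfinite(D) or np.ptp(g) == 0:
        raise DegenerateDesignError("all oriented gamma equal; slope not identifiable")
    slope = (Sw * Swxy - Swx * Swy) / D
    intercept = (Swxx * Swy - Swx * Swxy) / D
    se_slope = (Sw / D) ** 0.5
    se_intercept = (Swxx / D) ** 0.5
    Q = float(np.sum(w * (G - intercept - slope * g) ** 2))
    df = L - 2
    vm = _resolve_variance_model(variance_model, L)
    if vm == "multiplicative_random":
        infl = max(1.0, Q / df) ** 0.5
        se_slope *= infl
        se_intercept *= infl
    I2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    return MREstimate(
        method="egger",
        beta=float(slope),
        se=float(se_slope),
        ci_low=float(slope - Z_95 * se_slope),
        ci_high=float(slope + Z_95 * se_slope),
        pvalue=_two_sided_p(slope / se_slope),
        n_variants=L,
        Q=Q,
        Q_df=df,
        Q_pvalue=float(stats.chi2.sf(Q, df)),
        I2=I2,
        intercept=float(intercept),
        intercept_se=float(se_intercept),
        intercept_pvalue=_two_sided_p(intercept / se_intercept),
    )


def _weighted_median_1d(values: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated 50% weighted percentile.

    Sort values ascending, normalise weights, and evaluate the piecewise
    linear weighted empirical CDF at its cumulative midpoints
    ``p_j = S_j - w_j/2``.
    """
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order]
    w = w / w.sum()
    p = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, p, v))


def _weighted_median_rows(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise interpolated weighted median for (n, L) arrays."""
    order = np.argsort(values, axis=1, kind="stable")
    v = np.take_along_axis(values, order, axis=1)
    w = np.take_along_axis(weights, order, axis=1)
    w = w / w.sum(axis=1, keepdims=True)
    p = np.cumsum(w, axis=1) - 0.5 * w
    n, L = v.shape
    idx = np.sum(p < 0.5, axis=1)  # first index with p >= 0.5, in [0, L]
    out = np.empty(n)
    low = idx == 0
    high = idx == L
    out[low] = v[low, 0]
    out[high] = v[high, -1]
    mid = ~(low | high)
    i = idx[mid]
    rows = np.nonzero(mid)[0]
    p0 = p[rows, i - 1]
    p1 = p[rows, i]
    v0 = v[rows, i - 1]
    v1 = v[rows, i]
    frac = np.where(p1 > p0, (0.5 - p0) / np.where(p1 > p0, p1 - p0, 1.0), 0.0)
    out[mid] = v0 + frac * (v1 - v0)
    return out


def weighted_median(
    data: HarmonisedDataset,
    n_boot: int = 5000,
    seed: int | None = None,
) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Each bootstrap replicate redraws every variant's gamma and Gamma from
    ``Normal(gamma_j, se_gamma_j)`` and ``Normal(Gamma_j, se_Gamma_j)`` and
    recomputes the weighted median; the SE is the standard deviation of the
    replicates.  The same seed and inputs give bit-identical output.
    """
    L = data.n_variants
    if L < 3:
        raise InsufficientInstrumentsError(
            "weighted median requires at least 3 instruments"
        )
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    ratio = data.Gamma / data.gamma
    ratio_se = data.se_Gamma / np.abs(data.gamma)
    beta = _weighted_median_1d(ratio, ratio_se**-2.0)

    rng = np.random.default_rng(seed)
    g_b = data.gamma + data.se_gamma * rng.standard_normal((n_boot, L))
    G_b = data.Gamma + data.se_Gamma * rng.standard_normal((n_boot, L))
    # a resampled gamma of exactly 0 has measure zero; guard anyway
    g_b = np.where(g_b == 0.0, np.finfo(float).tiny, g_b)
    ratio_b = G_b / g_b
    w_b = (g_b / data.se_Gamma) ** 2
    boots = _weighted_median_rows(ratio_b, w_b)
    se = float(np.std(boots, ddof=1))
    return MREstimate(
        method="weighted_median",
        beta=float(beta),
        se=se,
        ci_low=float(beta - Z_95 * se),
        ci_high=float(beta + Z_95 * se),
        pvalue=_two_sided_p(beta / se),
        n_variants=L,
    )


def i2_gx(data: HarmonisedDataset) -> float:
    """Instrument-strength spread statistic I2_GX (diagnostic only).

    Computed from Q_GX = sum(se_gamma^-2 * (gamma - weighted mean)^2) over
    L-1 df; large values indicate a wide spread of instrument strengths.
    Classification never uses this quantity.
    """
    L = data.n_variants
    if L < 2:
        raise InsufficientInstrumentsError("I2_GX requires at least 2 instruments")
    w = data.se_gamma**-2.0
    gbar = float(np.sum(w * data.gamma) / np.sum(w))
    Q_gx = float(np.sum(w * (data.gamma - gbar) ** 2))
    if Q_gx <= 0:
        return 0.0
    return max(0.0, (Q_gx - (L - 1)) / Q_gx) * 100.0
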
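"""Cross-source random-effects meta-analysis of MR estimates.

The same exposure-outcome pair is estimated in two independent outcome
sources (a published GWAS and a biobank replication); the two per-source
IVW estimates are combined with a DerSimonian-Laird random-effects model.
The method-of-moments between-source variance tau^2 is

    tau^2 = max(0, (Q - (k-1)) / (sum(u) - sum(u^2)/sum(u)))

with fixed-effect weights u_i = se_i^-2 and Q the fixed-effect
heterogeneity statistic.  Random-effects weights are (se_i^2 + tau^2)^-1.
A single available source passes through unchanged with tau^2 = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .estimators import Z_95

__all__ = ["MetaResult", "random_effects_meta", "MetaError", "EmptyMetaInputError"]


class MetaError(Exception):
    pass


class EmptyMetaInputError(MetaError):
    pass


@dataclass
class MetaResult:
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    tau2: float
    Q_meta: float
    k: int


def random_effects_meta(estimates: Sequence[tuple[float, float]]) -> MetaResult:
    """DerSimonian-Laird combination of (beta, se) pairs.

    Raises :class:`EmptyMetaInputError` for an empty list and ``ValueError``
    for non-positive standard errors.
    """
    if len(estimates) == 0:
        raise EmptyMetaInputError("no estimates to combine")
    beta_i = np.array([b for b, _ in estimates], dtype=float)
    se_i = np.array([s for _, s in estimates], dtype=float)
    if np.any(se_i <= 0):
        raise ValueError("all standard errors must be positive")
    k = len(beta_i)
    u = se_i**-2.0
    beta_fixed = float(np.sum(u * beta_i) / np.sum(u))
    Q = float(np.sum(u * (beta_i - beta_fixed) ** 2))
    if k == 1:
        tau2 = 0.0
        beta = float(beta_i[0])
        se = float(se_i[0])
    else:
        c = float(np.sum(u) - np.sum(u**2) / np.sum(u))
        tau2 = max(0.0, (Q - (k - 1)) / c) if c > 0 else 0.0
        v = (se_i**2 + tau2) ** -1.0
        beta = float(np.sum(v * beta_i) / np.sum(v))
        se = float(np.sum(v) ** -0.5)
    z = beta / se
    return MetaResult(
        beta=beta,
        se=se,
        ci_low=beta - Z_95 * se,
        ci_high=beta + Z_95 * se,
        pvalue=float(max(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny)),
        tau2=tau2,
        Q_meta=Q,
        k=k,
    )
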
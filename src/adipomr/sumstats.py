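"""Reading, validation and harmonisation of GWAS summary statistics.

Two-sample MR needs per-variant effects from an exposure GWAS (SD units for
continuous exposures) and an outcome GWAS (log-odds for disease outcomes),
aligned so that both refer to the same effect allele.  This module reads
delimited summary-statistic tables, validates them row by row, and joins an
exposure table with an outcome table into an analysis-ready
:class:`HarmonisedDataset`.

Harmonisation rules
-------------------
Variants are matched by rsID.  When the outcome study reports the alleles
swapped relative to the exposure study, the outcome effect is sign-flipped
and its effect-allele frequency replaced by ``1 - eaf``.  Non-palindromic
allele pairs reported on the opposite strand are complement-matched
automatically.  Palindromic variants (A/T or G/C) cannot be strand-resolved
from alleles alone; they are either dropped (default) or aligned by
comparing allele frequencies to 0.5, with an ambiguity window around 0.5
inside which the variant is dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantAssociation",
    "HarmonisedDataset",
    "read_summary_stats",
    "harmonise",
    "is_palindromic",
    "SumstatsError",
    "ConfigurationError",
    "EmptyInputError",
    "EmptyOverlapError",
]

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: logical column name -> default physical column name
DEFAULT_COLUMN_MAP = {
    "variant_id": "variant_id",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "beta": "beta",
    "se": "se",
    "eaf": "eaf",
    "pvalue": "pvalue",
}

REQUIRED_COLUMNS = ("variant_id", "effect_allele", "other_allele", "beta", "se")


class SumstatsError(Exception):
    """Base class for summary-statistics errors."""


class ConfigurationError(SumstatsError):
    """A required column mapping or configuration entry is missing."""


class EmptyInputError(SumstatsError):
    """A summary-statistics table contained no valid rows."""


class EmptyOverlapError(SumstatsError):
    """Exposure and outcome tables share no variant IDs."""


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's association with one trait in one study.

    ``beta`` is on the SD scale for continuous exposures and the log-odds
    scale for disease outcomes.  ``eaf`` is the effect-allele frequency and
    may be missing (``None``).
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: float | None = None
    pvalue: float | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise ValueError(f"invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise ValueError(f"invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError("effect and other allele must differ")
        if not (self.se > 0):
            raise ValueError("se must be positive")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            raise ValueError("eaf must lie in (0, 1)")


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True for A/T and G/C pairs, whose strand cannot be resolved."""
    return COMPLEMENT[effect_allele] == other_allele


@dataclass
class HarmonisedDataset:
    """Aligned per-variant exposure (gamma) and outcome (Gamma) effects.

    One dataset corresponds to a single exposure-outcome-source triple.
    ``dropped`` records every variant from the ID intersection that was
    excluded, with a reason, so that ``len(variant_id) + len(dropped)``
    equals the size of the intersection.
    """

    exposure_name: str
    outcome_name: str
    source_name: str
    variant_id: np.ndarray
    gamma: np.ndarray
    se_gamma: np.ndarray
    Gamma: np.ndarray
    se_Gamma: np.ndarray
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.variant_id = np.asarray(self.variant_id, dtype=object)
        for name in ("gamma", "se_gamma", "Gamma", "se_Gamma"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.variant_id)
        for name in ("gamma", "se_gamma", "Gamma", "se_Gamma"):
            if len(getattr(self, name)) != n:
                raise ValueError("all record arrays must have equal length")
        if n:
            if len(set(self.variant_id.tolist())) != n:
                raise ValueError("variant IDs must be unique")
            if np.any(self.se_gamma <= 0) or np.any(self.se_Gamma <= 0):
                raise ValueError("standard errors must be positive")
            if np.any(self.gamma == 0):
                raise ValueError("retained records must have nonzero gamma")

    @property
    def n_variants(self) -> int:
        return len(self.variant_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": self.variant_id,
                "gamma": self.gamma,
                "se_gamma": self.se_gamma,
                "Gamma": self.Gamma,
                "se_Gamma": self.se_Gamma,
            }
        )

    def to_tsv(self, path, drop_log_path=None) -> None:
        """Write records as TSV; optionally write the drop log as a sidecar."""
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
        if drop_log_path is not None:
            pd.DataFrame(self.dropped, columns=["variant_id", "reason"]).to_csv(
                drop_log_path, sep="\t", index=False
            )


def _detect_delimiter(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_summary_stats(
    path,
    column_map: Mapping[str, str] | None = None,
) -> tuple[list[VariantAssociation], list[tuple[int, str]]]:
    """Read a delimited summary-statistics table.

    Parameters
    ----------
    path
        TSV or CSV file with a header line; the delimiter is auto-detected
        from the header.
    column_map
        Mapping from logical names (``variant_id``, ``effect_allele``,
        ``other_allele``, ``beta``, ``se``, optionally ``eaf``, ``pvalue``)
        to the physical column names in the file.  Unmapped logical names
        fall back to their own name.

    Returns
    -------
    records, diagnostics
        ``records`` in file order; ``diagnostics`` is a list of
        ``(row_index, reason)`` pairs for rejected rows (0-based data rows).

    Raises
    ------
    ConfigurationError
        if a mapped required column is absent from the file.
    EmptyInputError
        if no valid rows remain.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    sep = _detect_delimiter(path)
    table = pd.read_csv(path, sep=sep, dtype=str)
    for logical in REQUIRED_COLUMNS:
        if cmap[logical] not in table.columns:
            raise ConfigurationError(
                f"required column {cmap[logical]!r} (for {logical!r}) not found in {path}"
            )
    has_eaf = cmap["eaf"] in table.columns
    has_p = cmap["pvalue"] in table.columns

    records: list[VariantAssociation] = []
    diagnostics: list[tuple[int, str]] = []
    for i, row in enumerate(table.itertuples(index=False)):
        r = dict(zip(table.columns, row))
        try:
            beta = float(r[cmap["beta"]])
            se = float(r[cmap["se"]])
        except (TypeError, ValueError):
            diagnostics.append((i, "non-numeric beta or SE"))
            continue
        if not (math.isfinite(beta) and math.isfinite(se)):
            diagnostics.append((i, "non-numeric beta or SE"))
            continue
        if se <= 0:
            diagnostics.append((i, "non-positive SE"))
            continue
        ea = str(r[cmap["effect_allele"]]).strip().upper()
        oa = str(r[cmap["other_allele"]]).strip().upper()
        if ea not in VALID_ALLELES or oa not in VALID_ALLELES or ea == oa:
            diagnostics.append((i, "invalid alleles"))
            continue
        eaf = None
        if has_eaf:
            raw = r[cmap["eaf"]]
            try:
                val = float(raw)
                if 0.0 < val < 1.0:
                    eaf = val
            except (TypeError, ValueError):
                eaf = None
        pvalue = None
        if has_p:
            try:
                pvalue = float(r[cmap["pvalue"]])
            except (TypeError, ValueError):
                pvalue = None
        records.append(
            VariantAssociation(
                variant_id=str(r[cmap["variant_id"]]).strip(),
                effect_allele=ea,
                other_allele=oa,
                beta=beta,
                se=se,
                eaf=eaf,
                pvalue=pvalue,
            )
        )
    if not records:
        raise EmptyInputError(f"no valid rows in {path}")
    return records, diagnostics


def _align(
    exp: VariantAssociation,
    out: VariantAssociation,
    palindrome_policy: str,
    eaf_window: float,
) -> tuple[float | None, float | None, str | None]:
    """Return (sign, outcome_eaf, drop_reason) for one shared variant.

    ``sign`` multiplies the outcome beta; exactly one of (sign, reason) is
    not None.
    """
    if is_palindromic(exp.effect_allele, exp.other_allele):
        if palindrome_policy == "drop":
            return None, None, "palindromic"
        # infer_by_eaf: alleles alone cannot resolve strand; use frequency.
        if exp.eaf is None or out.eaf is None:
            return None, None, "palindromic, missing frequency"
        if abs(exp.eaf - 0.5) < eaf_window or abs(out.eaf - 0.5) < eaf_window:
            return None, None, "palindromic, ambiguous frequency"
        if (exp.eaf < 0.5) == (out.eaf < 0.5):
            return 1.0, out.eaf, None
        return -1.0, 1.0 - out.eaf, None

    ea, oa = exp.effect_allele, exp.other_allele
    pairs = [
        (out.effect_allele, out.other_allele, 1.0),
        (out.other_allele, out.effect_allele, -1.0),
        (COMPLEMENT[out.effect_allele], COMPLEMENT[out.other_allele], 1.0),
        (COMPLEMENT[out.other_allele], COMPLEMENT[out.effect_allele], -1.0),
    ]
    for cand_ea, cand_oa, sign in pairs:
        if cand_ea == ea and cand_oa == oa:
            eaf = out.eaf
            if eaf is not None and sign < 0:
                eaf = 1.0 - eaf
            return sign, eaf, None
    return None, None, "allele mismatch"


def harmonise(
    exposure: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    palindrome_policy: str = "drop",
    eaf_window: float = 0.08,
    *,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
    source_name: str = "source",
) -> HarmonisedDataset:
    """Align an outcome table to an exposure table into one dataset.

    The ID intersection of the two tables is partitioned into retained
    records and dropped variants.  Variants with a zero exposure effect are
    dropped (the Wald ratio is undefined for them).

    Raises
    ------
    EmptyOverlapError
        if the two tables share no variant IDs.
    ValueError
        for an unknown ``palindrome_policy``.
    """
    if palindrome_policy not in ("drop", "infer_by_eaf"):
        raise ValueError(f"unknown palindrome_policy {palindrome_policy!r}")
    exp_by_id = {v.variant_id: v for v in exposure}
    out_by_id = {v.variant_id: v for v in outcome}
    shared = [v.variant_id for v in exposure if v.variant_id in out_by_id]
    if not shared:
        raise EmptyOverlapError(
            f"no shared variants between {exposure_name} and "
            f"{outcome_name} ({source_name})"
        )

    ids: list[str] = []
    gamma: list[float] = []
    se_gamma: list[float] = []
    Gam: list[float] = []
    se_Gam: list[float] = []
    dropped: list[tuple[str, str]] = []
    for vid in shared:
        exp, out = exp_by_id[vid], out_by_id[vid]
        sign, _eaf, reason = _align(exp, out, palindrome_policy, eaf_window)
        if reason is not None:
            dropped.append((vid, reason))
            continue
        if exp.beta == 0:
            dropped.append((vid, "zero exposure effect"))
            continue
        ids.append(vid)
        gamma.append(exp.beta)
        se_gamma.append(exp.se)
        Gam.append(sign * out.beta)
        se_Gam.append(out.se)
    return HarmonisedDataset(
        exposure_name=exposure_name,
        outcome_name=outcome_name,
        source_name=source_name,
        variant_id=np.array(ids, dtype=object),
        gamma=np.array(gamma, dtype=float),
        se_gamma=np.array(se_gamma, dtype=float),
        Gamma=np.array(Gam, dtype=float),
        se_Gamma=np.array(se_Gam, dtype=float),
        dropped=dropped,
    )
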
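"""Study orchestration: per-source MR, meta-analysis, FDR, classification.

``run_pipeline`` executes the full design over TSV summary-statistic
inputs: for every exposure-outcome-source combination it harmonises the
tables and runs IVW, MR-Egger and the weighted median; per-source IVW
estimates are combined across meta-eligible sources with a random-effects
model; Benjamini-Hochberg FDR is applied per exposure across the disease
panel, separately for the meta arm and the validation arm (the validation
arm never feeds classification, because its exposure weights were largely
discovered in the same cohort); and each disease is assigned its
causal-component category from the meta arm.

Every excluded variant, skipped source and gate decision is recorded in a
structured line-per-event log.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import estimators as _est
from . import meta as _meta
from . import sumstats as _ss

__all__ = ["RunConfig", "PipelineResult", "load_config", "run_pipeline",
           "write_outputs", "expected_null_count", "PipelineConfigError"]


class PipelineConfigError(Exception):
    pass


@dataclass
class SourceSpec:
    name: str
    path: Path
    meta_eligible: bool = True
    exposures: list[str] | None = None  # optional per-source exposure subset


@dataclass
class OutcomeSpec:
    disease: str
    sources: list[SourceSpec]


@dataclass
class RunConfig:
    exposures: dict[str, Path]
    outcomes: list[OutcomeSpec]
    fdr_threshold: float = 0.1
    variance_model: str | None = None  # None = fixed for L<4, multiplicative for L>=4
    n_boot: int = 5000
    seed: int = 0
    palindrome_policy: str = "drop"
    eaf_window: float = 0.08
    output_dir: Path = Path("results")

    def validate(self) -> None:
        if not self.exposures:
            raise PipelineConfigError("at least one exposure is required")
        if not self.outcomes:
            raise PipelineConfigError("at least one outcome is required")
        for name, path in self.exposures.items():
            if not Path(path).exists():
                raise PipelineConfigError(f"exposure table not found: {path}")
        for out in self.outcomes:
            for src in out.sources:
                if not Path(src.path).exists():
                    raise PipelineConfigError(
                        f"outcome table not found: {src.path} "
                        f"({out.disease}/{src.name})"
                    )
        if not (0.0 < self.fdr_threshold < 1.0):
            raise PipelineConfigError("fdr_threshold must lie in (0, 1)")


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; relative paths resolve next to it."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    base = path.parent

    def resolve(p) -> Path:
        p = Path(p)
        return p if p.is_absolute() else base / p

    exposures = {e["name"]: resolve(e["path"]) for e in raw["exposures"]}
    outcomes = []
    for o in raw["outcomes"]:
        sources = [
            SourceSpec(
                name=s["name"],
                path=resolve(s["path"]),
                meta_eligible=bool(s.get("meta_eligible", True)),
                exposures=s.get("exposures"),
            )
            for s in o["sources"]
        ]
        outcomes.append(OutcomeSpec(disease=o["disease"], sources=sources))
    return RunConfig(
        exposures=exposures,
        outcomes=outcomes,
        fdr_threshold=float(raw.get("fdr_threshold", 0.1)),
        variance_model=raw.get("variance_model"),
        n_boot=int(raw.get("n_boot", 5000)),
        seed=int(raw.get("seed", 0)),
        palindrome_policy=raw.get("palindrome_policy", "drop"),
        eaf_window=float(raw.get("eaf_window", 0.08)),
        output_dir=resolve(raw.get("output_dir", "results")),
    )


@dataclass
class PipelineResult:
    estimates: pd.DataFrame  # one row per exposure x outcome x source x method
    meta: pd.DataFrame  # meta-analysed IVW per exposure x outcome (+ q-values)
    validation: pd.DataFrame  # validation-arm IVW (+ q-values), annotation only
    verdicts: pd.DataFrame  # one row per disease
    sensitivity: dict[str, Any]
    log: list[str] = field(default_factory=list)


def _wm_seed(master_seed: int, exposure: str, disease: str, source: str) -> int:
    """Stable per-combination bootstrap seed (crc32 is platform-stable)."""
    key = f"{exposure}|{disease}|{source}".encode()
    return (int(master_seed) ^ zlib.crc32(key)) % (2**31)


def expected_null_count(
    n_diseases: int, n_exposures: int, alpha: float
) -> tuple[float, int]:
    """Expected number of significant tests under the global null.

    Returns ``(alpha * n_diseases * n_exposures, nearest integer)`` — e.g.
    37 diseases x 4 exposures at alpha 0.05 gives 7.4, rounding to 7.
    """
    if n_diseases < 1 or n_exposures < 1:
        raise ValueError("counts must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    expected = alpha * n_diseases * n_exposures
    return expected, int(round(expected))


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full study over the configured tables."""
    config.validate()
    log: list[str] = []
    exposure_records: dict[str, list[_ss.VariantAssociation]] = {}
    for name, path in config.exposures.items():
        records, diags = _ss.read_summary_stats(path)
        for row, reason in diags:
            log.append(f"read\texposure={name}\trow={row}\trejected: {reason}")
        exposure_records[name] = records
        log.append(f"read\texposure={name}\tn={len(records)}")

    est_rows: list[dict] = []
    # per (exposure, disease): list of (source, MREstimate) for meta arm
    meta_inputs: dict[tuple[str, str], list[tuple[str, _est.MREstimate]]] = {}
    validation_ivw: dict[tuple[str, str], _est.MREstimate] = {}

    for outcome in config.outcomes:
        usable_sources = 0
        for src in outcome.sources:
            try:
                out_records, diags = _ss.read_summary_stats(src.path)
            except _ss.EmptyInputError as exc:
                log.append(f"skip\t{outcome.disease}/{src.name}\t{exc}")
                continue
            for row, reason in diags:
                log.append(
                    f"read\t{outcome.disease}/{src.name}\trow={row}\trejected: {reason}"
                )
            usable_sources += 1
            allowed = src.exposures or list(config.exposures)
            for exposure in config.exposures:
                if exposure not in allowed:
                    log.append(
                        f"skip\t{exposure}\t{outcome.disease}/{src.name}\t"
                        "exposure not available in this source"
                    )
                    continue
                try:
                    data = _ss.harmonise(
                        exposure_records[exposure],
                        out_records,
                        palindrome_policy=config.palindrome_policy,
                        eaf_window=config.eaf_window,
                        exposure_name=exposure,
                        outcome_name=outcome.disease,
                        source_name=src.name,
                    )
                except _ss.EmptyOverlapError as exc:
                    log.append(f"skip\t{exposure}\t{outcome.disease}/{src.name}\t{exc}")
                    continue
                for vid, reason in data.dropped:
                    log.append(
                        f"drop\t{exposure}\t{outcome.disease}/{src.name}\t{vid}\t{reason}"
                    )
                if data.n_variants == 0:
                    log.append(
                        f"skip\t{exposure}\t{outcome.disease}/{src.name}\t"
                        "no variants after harmonisation"
                    )
                    continue
                estimates = [_est.ivw(data, config.variance_model)]
                if data.n_variants >= 3:
                    try:
                        estimates.append(_est.egger(data, config.variance_model))
                    except _est.DegenerateDesignError as exc:
                        log.append(
                            f"skip\tegger\t{exposure}\t{outcome.disease}/{src.name}\t{exc}"
                        )
                    estimates.append(
                        _est.weighted_median(
                            data,
                            n_boot=config.n_boot,
                            seed=_wm_seed(
                                config.seed, exposure, outcome.disease, src.name
                            ),
                        )
                    )
                else:
                    log.append(
                        f"skip\tegger+wm\t{exposure}\t{outcome.disease}/{src.name}\t"
                        f"only {data.n_variants} instrument(s)"
                    )
                for est in estimates:
                    row = {
                        "exposure": exposure,
                        "outcome": outcome.disease,
                        "source": src.name,
                        "meta_eligible": src.meta_eligible,
                    }
                    row.update(est.to_row())
                    est_rows.append(row)
                ivw_est = estimates[0]
                key = (exposure, outcome.disease)
                if src.meta_eligible:
                    meta_inputs.setdefault(key, []).append((src.name, ivw_est))
                else:
                    validation_ivw[key] = ivw_est
        if usable_sources == 0:
            log.append(f"skip\t{outcome.disease}\tno usable sources")

    estimates_df = pd.DataFrame(est_rows)

    # ---- meta-analysis of IVW across meta-eligible sources -----------------
    meta_rows: list[dict] = []
    for (exposure, disease), items in meta_inputs.items():
        result = _meta.random_effects_meta(
            [(e.beta, e.se) for _, e in items]
        )
        meta_rows.append(
            {
                "exposure": exposure,
                "outcome": disease,
                "source": "meta",
                "method": "ivw",
                "k": result.k,
                "beta": result.beta,
                "OR": float(np.exp(result.beta)),
                "se": result.se,
                "ci_low": result.ci_low,
                "ci_high": result.ci_high,
                "pvalue": result.pvalue,
                "tau2": result.tau2,
                "Q_meta": result.Q_meta,
            }
        )
    meta_df = pd.DataFrame(meta_rows)

    # ---- per-exposure BH FDR within each arm -------------------------------
    def add_qvalues(df: pd.DataFrame) -> pd.DataFrame:
        if df.empty:
            return df.assign(qvalue=pd.Series(dtype=float))
        df = df.copy()
        df["qvalue"] = np.nan
        for exposure, idx in df.groupby("exposure").groups.items():
            q = _classify.bh_fdr(df.loc[idx, "pvalue"].to_numpy())
            df.loc[idx, "qvalue"] = q
        return df

    meta_df = add_qvalues(meta_df)
    val_rows = [
        {
            "exposure": exposure,
            "outcome": disease,
            "source": "validation",
            "method": "ivw",
            "beta": e.beta,
            "OR": float(np.exp(e.beta)),
            "se": e.se,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
            "pvalue": e.pvalue,
        }
        for (exposure, disease), e in validation_ivw.items()
    ]
    validation_df = add_qvalues(pd.DataFrame(val_rows))

    # ---- classification from the meta arm ----------------------------------
    verdict_rows: list[dict] = []
    diseases = [o.disease for o in config.outcomes]
    meta_by_key = (
        {
            (r["exposure"], r["outcome"]): r
            for r in meta_df.to_dict("records")
        }
        if not meta_df.empty
        else {}
    )
    for disease in diseases:
        per_exposure = {}
        for exposure in config.exposures:
            r = meta_by_key.get((exposure, disease))
            if r is not None:
                per_exposure[exposure] = _classify.ExposureSummary(
                    beta=r["beta"], se=r["se"], pvalue=r["pvalue"], qvalue=r["qvalue"]
                )
        if "bmi" not in per_exposure:
            log.append(f"gate\t{disease}\tno meta-arm BMI estimate; not classified")
            continue
        verdict = _classify.classify_disease(
            disease, per_exposure, fdr_threshold=config.fdr_threshold
        )
        log.append(f"gate\t{disease}\tcategory={verdict.category}")
        row = {
            "disease": disease,
            "category": verdict.category,
            "protective_outcome": verdict.protective_outcome,
        }
        for exposure, s in verdict.per_exposure.items():
            row[f"{exposure}_beta"] = s.beta
            row[f"{exposure}_OR"] = float(np.exp(s.beta))
            row[f"{exposure}_se"] = s.se
            row[f"{exposure}_pvalue"] = s.pvalue
            row[f"{exposure}_qvalue"] = s.qvalue
        verdict_rows.append(row)
    verdicts_df = pd.DataFrame(verdict_rows)

    sensitivity = _sensitivity_report(estimates_df, meta_df, validation_df)
    return PipelineResult(
        estimates=estimates_df,
        meta=meta_df,
        validation=validation_df,
        verdicts=verdicts_df,
        sensitivity=sensitivity,
        log=log,
    )


def classify_synthetic_study(
    study,
    fdr_threshold: float = 0.1,
    variance_model: str | None = None,
) -> tuple[dict[str, _classify.DiseaseVerdict], dict[tuple[str, str], _meta.MetaResult]]:
    """IVW + meta-analysis + per-exposure BH + classification, in memory.

    Convenience runner for a :class:`~adipomr.simulate.SyntheticStudy`:
    identical stage-by-stage to :func:`run_pipeline`'s meta arm but without
    the text round trip.  Returns ``(verdicts by disease, meta results by
    (exposure, disease))``.
    """
    exposures = list(study.panel.observed)
    results: dict[tuple[str, str], _meta.MetaResult] = {}
    for name, data in study.diseases.items():
        for exposure in exposures:
            per_source = [
                _est.ivw(data.harmonised(exposure, s), variance_model)
                for s in data.meta_sources()
            ]
            results[(exposure, name)] = _meta.random_effects_meta(
                [(e.beta, e.se) for e in per_source]
            )
    diseases = list(study.diseases)
    qvalues: dict[tuple[str, str], float] = {}
    for exposure in exposures:
        q = _classify.bh_fdr([results[(exposure, d)].pvalue for d in diseases])
        for d, qq in zip(diseases, q):
            qvalues[(exposure, d)] = float(qq)
    verdicts: dict[str, _classify.DiseaseVerdict] = {}
    for d in diseases:
        per_exposure = {
            e: _classify.ExposureSummary(
                beta=results[(e, d)].beta,
                se=results[(e, d)].se,
                pvalue=results[(e, d)].pvalue,
                qvalue=qvalues[(e, d)],
            )
            for e in exposures
        }
        verdicts[d] = _classify.classify_disease(
            d, per_exposure, fdr_threshold=fdr_threshold
        )
    return verdicts, results


def _sensitivity_report(
    estimates: pd.DataFrame, meta: pd.DataFrame, validation: pd.DataFrame
) -> dict[str, Any]:
    """Directional-consistency counts of sensitivity analyses versus IVW."""
    report: dict[str, Any] = {}
    if estimates.empty:
        return report
    ivw = estimates[estimates["method"].isin(["ivw", "wald_ratio"])]
    for method in ("weighted_median", "egger"):
        alt = estimates[estimates["method"] == method]
        merged = ivw.merge(
            alt,
            on=["exposure", "outcome", "source"],
            suffixes=("_ivw", f"_{method}"),
        )
        if merged.empty:
            continue
        same = np.sign(merged["beta_ivw"]) == np.sign(merged[f"beta_{method}"])
        report[f"{method}_vs_ivw"] = {
            "n": int(len(merged)),
            "directionally_consistent": int(same.sum()),
        }
    if not meta.empty and not validation.empty:
        merged = meta.merge(
            validation, on=["exposure", "outcome"], suffixes=("_meta", "_val")
        )
        if not merged.empty:
            same = np.sign(merged["beta_meta"]) == np.sign(merged["beta_val"])
            report["validation_vs_meta"] = {
                "n": int(len(merged)),
                "directionally_consistent": int(same.sum()),
                "validation_p_lt_05": int((merged["pvalue_val"] < 0.05).sum()),
            }
    return report


def write_outputs(result: PipelineResult, outdir) -> None:
    """Write estimate, meta, verdict tables, sensitivity report and log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    kw = dict(sep="\t", index=False, float_format="%.10g")
    result.estimates.to_csv(outdir / "estimates.tsv", **kw)
    result.meta.to_csv(outdir / "meta.tsv", **kw)
    result.validation.to_csv(outdir / "validation.tsv", **kw)
    result.verdicts.to_csv(outdir / "verdicts.tsv", **kw)
    with open(outdir / "sensitivity.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(result.sensitivity, fh, sort_keys=True)
    with open(outdir / "run.log", "w", encoding="utf-8") as fh:
        fh.write("\n".join(result.log) + "\n")
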
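"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the study design of an adiposity-component MR
analysis: four instrument sets (73 BMI, 696 body-fat-percentage, 36
favourable-adiposity FA and 38 unfavourable-adiposity UFA variants, with 5
variants shared between the BMI and BFP sets) against a panel of disease
outcomes observed in two meta-analysable sources plus one validation
source.

Causal model
------------
Each variant j carries a true adiposity effect ``gamma*_j`` (SD per allele,
folded-normal so instruments point at higher adiposity) and a metabolic
loading ``m_j``: FA variants load ``-m`` (higher adiposity, *better*
metabolic profile), UFA variants ``+m``, and generic BMI/BFP variants a
positive-mean mixture (higher adiposity is, on average, metabolically
adverse).  A disease's true per-allele outcome effect is

    Gamma*_j = theta_mech * gamma*_j + theta_met * m_j + e_j

where ``theta_mech`` is the causal effect of adiposity per se and
``theta_met`` the effect of the metabolic pathway (both log-odds per SD),
and ``e_j`` is optional balanced or directional pleiotropy.  Observed
effects add independent normal sampling noise: exposure effects once per
exposure GWAS (shared across outcome sources, as in a real two-sample
design with one exposure study), outcome effects independently per source.

Instrument strength is calibrated so per-variant ``gamma/se_gamma`` is
about 6-10, matching genome-wide-significant instruments.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats as _st

from .sumstats import COMPLEMENT, HarmonisedDataset

__all__ = [
    "SyntheticConfig",
    "DiseaseSpec",
    "InstrumentPanel",
    "DiseaseData",
    "simulate_instruments",
    "simulate_two_sample",
    "simulate_study",
    "write_study",
    "SimulationConfigError",
]

EXPOSURES = ("bmi", "bfp", "fa", "ufa")
DEFAULT_THETA = 0.4

NON_PALINDROMIC_PAIRS = [
    (a, b)
    for a, b in itertools.permutations("ACGT", 2)
    if COMPLEMENT[a] != b
]
PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")]


class SimulationConfigError(Exception):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the two-pathway summary-statistics simulator.

    Instrument counts default to the study design being emulated; effect
    scales are free parameters chosen to give realistic per-variant effect
    sizes (a few hundredths of an SD per allele) and instrument strength.
    """

    L_bmi: int = 73
    L_bfp: int = 696
    L_fa: int = 36
    L_ufa: int = 38
    n_overlap_bmi_bfp: int = 5
    #: mean per-allele adiposity effect (SD units) and its spread
    adiposity_scale: float = 0.03
    adiposity_sd: float = 0.012
    #: per-allele metabolic-pathway loading magnitude (FA -m, UFA +m)
    met_scale: float = 0.03
    met_loading_sd: float = 0.25
    #: metabolic tilt of generic BMI/BFP variants (mean, sd of the mixture)
    bmi_met_tilt: float = 0.6
    bmi_met_tilt_sd: float = 0.4
    #: per-variant exposure z-score range (genome-wide-significant strength)
    instrument_z_low: float = 6.0
    instrument_z_high: float = 10.0
    se_gamma_scale: float = 1.0
    se_Gamma_scale: float = 0.01
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    palindromic_fraction: float = 0.1
    n_meta_sources: int = 2
    include_validation: bool = True
    n_diseases: int = 37

    def validate(self) -> None:
        for name in ("L_bmi", "L_bfp", "L_fa", "L_ufa"):
            if getattr(self, name) < 1:
                raise SimulationConfigError(f"{name} must be >= 1")
        if self.n_overlap_bmi_bfp < 0 or self.n_overlap_bmi_bfp > min(
            self.L_bmi, self.L_bfp
        ):
            raise SimulationConfigError(
                "n_overlap_bmi_bfp must not exceed either instrument set"
            )
        for name in ("adiposity_scale", "met_scale", "se_gamma_scale", "se_Gamma_scale"):
            if getattr(self, name) <= 0:
                raise SimulationConfigError(f"{name} must be > 0")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise SimulationConfigError(
                f"unknown pleiotropy_mode {self.pleiotropy_mode!r}"
            )
        if not (0.0 <= self.palindromic_fraction <= 1.0):
            raise SimulationConfigError("palindromic_fraction must lie in [0, 1]")
        if self.n_meta_sources < 1:
            raise SimulationConfigError("n_meta_sources must be >= 1")


@dataclass(frozen=True)
class DiseaseSpec:
    """Which causal pathways drive a synthetic disease.

    ``kind`` is one of ``metabolic_only``, ``mechanical_only``, ``mixed``
    or ``null``.  For ``mixed`` both thetas must be given; for the *_only
    kinds the active theta defaults to 0.4 log-odds per SD.
    """

    kind: str
    theta_met: float | None = None
    theta_mech: float | None = None

    def resolve(self) -> tuple[float, float]:
        """Return (theta_mech, theta_met)."""
        if self.kind == "metabolic_only":
            return 0.0, DEFAULT_THETA if self.theta_met is None else self.theta_met
        if self.kind == "mechanical_only":
            return (DEFAULT_THETA if self.theta_mech is None else self.theta_mech), 0.0
        if self.kind == "mixed":
            if self.theta_met is None or self.theta_mech is None:
                raise SimulationConfigError(
                    "mixed disease_spec requires theta_met and theta_mech"
                )
            return self.theta_mech, self.theta_met
        if self.kind == "null":
            return 0.0, 0.0
        raise SimulationConfigError(f"unknown disease_spec kind {self.kind!r}")


def _rng(seed: int, *stream: int) -> np.random.Generator:
    """Deterministic child stream split from the master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, stream)]))


@dataclass
class InstrumentPanel:
    """Master instrument truth plus per-exposure observed association tables.

    ``master`` holds one row per unique variant with its true adiposity
    effect and metabolic loading; ``observed[exposure]`` holds the noisy
    exposure-GWAS association table (exposure-trait-specific weights, so
    BMI/BFP-shared variants appear in both with independent estimates).
    ``index[exposure]`` gives each exposure's integer positions into the
    master table.
    """

    master: pd.DataFrame
    observed: dict[str, pd.DataFrame]
    index: dict[str, np.ndarray]

    def exposure_ids(self, exposure: str) -> np.ndarray:
        return self.master["variant_id"].to_numpy()[self.index[exposure]]


def simulate_instruments(config: SyntheticConfig, seed: int) -> InstrumentPanel:
    """Draw instrument truth tables and per-exposure observed effects."""
    config.validate()
    n_shared = config.n_overlap_bmi_bfp
    n_unique = (
        config.L_bmi + config.L_bfp - n_shared + config.L_fa + config.L_ufa
    )
    rng = _rng(seed, 0)

    variant_id = np.array([f"rs{i + 1:06d}" for i in range(n_unique)], dtype=object)
    # membership layout: [bmi (incl shared at front)] [bfp-only] [fa] [ufa]
    idx_bmi = np.arange(config.L_bmi)
    idx_bfp = np.concatenate(
        [np.arange(n_shared), config.L_bmi + np.arange(config.L_bfp - n_shared)]
    )
    off = config.L_bmi + config.L_bfp - n_shared
    idx_fa = off + np.arange(config.L_fa)
    idx_ufa = off + config.L_fa + np.arange(config.L_ufa)

    gamma_true = np.abs(
        rng.normal(config.adiposity_scale, config.adiposity_sd, n_unique)
    )
    gamma_true = np.maximum(gamma_true, 1e-4)

    m_loading = np.zeros(n_unique)
    generic = np.ones(n_unique, dtype=bool)
    generic[idx_fa] = False
    generic[idx_ufa] = False
    m_loading[generic] = config.met_scale * rng.normal(
        config.bmi_met_tilt, config.bmi_met_tilt_sd, int(generic.sum())
    )
    m_loading[idx_fa] = -config.met_scale * np.abs(
        rng.normal(1.0, config.met_loading_sd, config.L_fa)
    )
    m_loading[idx_ufa] = config.met_scale * np.abs(
        rng.normal(1.0, config.met_loading_sd, config.L_ufa)
    )

    pal = rng.random(n_unique) < config.palindromic_fraction
    pal_choice = rng.integers(0, len(PALINDROMIC_PAIRS), n_unique)
    non_pal_choice = rng.integers(0, len(NON_PALINDROMIC_PAIRS), n_unique)
    effect_allele = np.empty(n_unique, dtype=object)
    other_allele = np.empty(n_unique, dtype=object)
    for i in range(n_unique):
        ea, oa = (
            PALINDROMIC_PAIRS[pal_choice[i]]
            if pal[i]
            else NON_PALINDROMIC_PAIRS[non_pal_choice[i]]
        )
        effect_allele[i] = ea
        other_allele[i] = oa
    eaf = rng.uniform(0.05, 0.95, n_unique)

    master = pd.DataFrame(
        {
            "variant_id": variant_id,
            "effect_allele": effect_allele,
            "other_allele": other_allele,
            "eaf": eaf,
            "gamma_true": gamma_true,
            "m_loading": m_loading,
            "in_bmi": np.isin(np.arange(n_unique), idx_bmi),
            "in_bfp": np.isin(np.arange(n_unique), idx_bfp),
            "in_fa": np.isin(np.arange(n_unique), idx_fa),
            "in_ufa": np.isin(np.arange(n_unique), idx_ufa),
        }
    )

    index = {"bmi": idx_bmi, "bfp": idx_bfp, "fa": idx_fa, "ufa": idx_ufa}
    observed: dict[str, pd.DataFrame] = {}
    for k, exposure in enumerate(EXPOSURES):
        idx = index[exposure]
        erng = _rng(seed, 1, k)
        z = erng.uniform(config.instrument_z_low, config.instrument_z_high, len(idx))
        se = config.se_gamma_scale * gamma_true[idx] / z
        beta = gamma_true[idx] + se * erng.standard_normal(len(idx))
        observed[exposure] = pd.DataFrame(
            {
                "variant_id": variant_id[idx],
                "effect_allele": effect_allele[idx],
                "other_allele": other_allele[idx],
                "eaf": eaf[idx],
                "beta": beta,
                "se": se,
                "pvalue": 2.0 * _st.norm.sf(np.abs(beta / se)),
            }
        )
    return InstrumentPanel(master=master, observed=observed, index=index)


@dataclass
class DiseaseData:
    """One synthetic disease: outcome truth and per-source observations."""

    name: str
    spec: DiseaseSpec
    panel: InstrumentPanel
    config: SyntheticConfig
    Gamma_true: np.ndarray
    pleiotropy: np.ndarray
    #: source name -> (Gamma_hat, se_Gamma) aligned to the master table
    sources: dict[str, tuple[np.ndarray, np.ndarray]]

    @property
    def source_names(self) -> list[str]:
        return list(self.sources)

    def meta_sources(self) -> list[str]:
        return [s for s in self.sources if s != "validation"]

    def harmonised(self, exposure: str, source: str) -> HarmonisedDataset:
        """Analysis-ready dataset, bypassing the text round trip.

        The generator knows the true allele orientation, so this join is
        exact; the TSV path through :func:`adipomr.sumstats.harmonise`
        exercises allele handling separately.
        """
        idx = self.panel.index[exposure]
        obs = self.panel.observed[exposure]
        Gh, sG = self.sources[source]
        return HarmonisedDataset(
            exposure_name=exposure,
            outcome_name=self.name,
            source_name=source,
            variant_id=obs["variant_id"].to_numpy(),
            gamma=obs["beta"].to_numpy(),
            se_gamma=obs["se"].to_numpy(),
            Gamma=Gh[idx],
            se_Gamma=sG[idx],
        )

    def truth_frame(self) -> pd.DataFrame:
        m = self.panel.master
        return pd.DataFrame(
            {
                "variant_id": m["variant_id"],
                "gamma_true": m["gamma_true"],
                "m_loading": m["m_loading"],
                "pleiotropy": self.pleiotropy,
                "Gamma_true": self.Gamma_true,
            }
        )

    def outcome_table(self, source: str, shuffle_alleles: bool = True) -> pd.DataFrame:
        """Outcome summary-statistics table in the TSV dialect read by
        :func:`adipomr.sumstats.read_summary_stats`.

        With ``shuffle_alleles`` non-palindromic variants are randomly
        reported allele-swapped or strand-flipped (harmonisation must undo
        this); palindromic variants keep the exposure orientation.
        """
        m = self.panel.master
        Gh, sG = self.sources[source]
        ea = m["effect_allele"].to_numpy().copy()
        oa = m["other_allele"].to_numpy().copy()
        eaf = m["eaf"].to_numpy().copy()
        beta = Gh.copy()
        if shuffle_alleles:
            srng = _rng_for_source(self._shuffle_seed, source)
            pal = np.array(
                [COMPLEMENT[a] == b for a, b in zip(ea, oa)], dtype=bool
            )
            swap = (srng.random(len(ea)) < 0.5) & ~pal
            comp = (srng.random(len(ea)) < 0.5) & ~pal
            ea_s, oa_s = ea.copy(), oa.copy()
            ea_s[swap], oa_s[swap] = oa[swap], ea[swap]
            beta[swap] = -beta[swap]
            eaf[swap] = 1.0 - eaf[swap]
            for i in np.nonzero(comp)[0]:
                ea_s[i] = COMPLEMENT[ea_s[i]]
                oa_s[i] = COMPLEMENT[oa_s[i]]
            ea, oa = ea_s, oa_s
        return pd.DataFrame(
            {
                "variant_id": m["variant_id"],
                "effect_allele": ea,
                "other_allele": oa,
                "eaf": eaf,
                "beta": beta,
                "se": sG,
                "pvalue": 2.0 * _st.norm.sf(np.abs(beta / sG)),
            }
        )

    _shuffle_seed: int = 0


def _rng_for_source(seed: int, source: str) -> np.random.Generator:
    order = {"validation": 99}
    key = order.get(source)
    if key is None:
        key = int(source.split("_")[-1]) if source.split("_")[-1].isdigit() else 98
    return _rng(seed, 7, key)


def simulate_two_sample(
    config: SyntheticConfig,
    panel: InstrumentPanel,
    spec: DiseaseSpec,
    seed: int,
    name: str = "disease",
) -> DiseaseData:
    """Generate one disease's true and observed outcome effects.

    All sources share the same truth (including pleiotropy); observation
    noise is independent per source.  Source names are ``source_1``,
    ``source_2``, ... plus ``validation`` when configured.
    """
    theta_mech, theta_met = spec.resolve()
    m = panel.master
    n = len(m)
    trng = _rng(seed, 2)
    if config.pleiotropy_mode == "none":
        e = np.zeros(n)
    elif config.pleiotropy_mode == "balanced":
        e = trng.normal(0.0, config.pleiotropy_sd, n)
    else:  # directional
        e = trng.normal(config.pleiotropy_mean, config.pleiotropy_sd, n)
    Gamma_true = (
        theta_mech * m["gamma_true"].to_numpy()
        + theta_met * m["m_loading"].to_numpy()
        + e
    )

    source_names = [f"source_{i + 1}" for i in range(config.n_meta_sources)]
    if config.include_validation:
        source_names.append("validation")
    sources: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for s_i, s_name in enumerate(source_names):
        srng = _rng(seed, 3, s_i)
        se_G = config.se_Gamma_scale * srng.uniform(0.8, 1.2, n)
        Gh = Gamma_true + se_G * srng.standard_normal(n)
        sources[s_name] = (Gh, se_G)
    data = DiseaseData(
        name=name,
        spec=spec,
        panel=panel,
        config=config,
        Gamma_true=Gamma_true,
        pleiotropy=e,
        sources=sources,
    )
    data._shuffle_seed = seed
    return data


@dataclass
class SyntheticStudy:
    config: SyntheticConfig
    panel: InstrumentPanel
    diseases: dict[str, DiseaseData]
    seed: int


def simulate_study(
    config: SyntheticConfig,
    disease_specs: Sequence[tuple[str, DiseaseSpec]],
    seed: int,
) -> SyntheticStudy:
    """One instrument draw plus a panel of diseases sharing it."""
    panel = simulate_instruments(config, seed)
    diseases = {
        name: simulate_two_sample(config, panel, spec, seed=_disease_seed(seed, i), name=name)
        for i, (name, spec) in enumerate(disease_specs)
    }
    return SyntheticStudy(config=config, panel=panel, diseases=diseases, seed=seed)


def _disease_seed(seed: int, i: int) -> int:
    # deterministic, collision-free per-disease sub-seed
    return int(np.random.SeedSequence([int(seed), 5, int(i)]).generate_state(1)[0] % (2**31))


def write_study(study: SyntheticStudy, outdir, shuffle_alleles: bool = True) -> Path:
    """Write a study as TSV tables plus a ready-to-run pipeline config.

    Layout: ``exposures/<exposure>.tsv``, ``outcomes/<disease>/<source>.tsv``,
    ``truth/<disease>.tsv`` and ``run_config.yaml``.  Returns the config
    path.
    """
    outdir = Path(outdir)
    (outdir / "exposures").mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)
    for exposure, table in study.panel.observed.items():
        table.to_csv(
            outdir / "exposures" / f"{exposure}.tsv",
            sep="\t",
            index=False,
            float_format="%.10g",
        )
    outcome_cfg = []
    for name, data in study.diseases.items():
        ddir = outdir / "outcomes" / name
        ddir.mkdir(parents=True, exist_ok=True)
        srcs = []
        for source in data.source_names:
            path = ddir / f"{source}.tsv"
            data.outcome_table(source, shuffle_alleles=shuffle_alleles).to_csv(
                path, sep="\t", index=False, float_format="%.10g"
            )
            srcs.append(
                {
                    "name": source,
                    "path": str(path.relative_to(outdir)),
                    "meta_eligible": source != "validation",
                }
            )
        data.truth_frame().to_csv(
            outdir / "truth" / f"{name}.tsv", sep="\t", index=False, float_format="%.10g"
        )
        outcome_cfg.append({"disease": name, "sources": srcs})
    run_config = {
        "seed": int(study.seed),
        "fdr_threshold": 0.1,
        "palindrome_policy": "infer_by_eaf",
        "eaf_window": 0.08,
        "n_boot": 5000,
        "exposures": [
            {"name": e, "path": f"exposures/{e}.tsv"} for e in study.panel.observed
        ],
        "outcomes": outcome_cfg,
        "output_dir": "results",
    }
    cfg_path = outdir / "run_config.yaml"
    with open(cfg_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(run_config, fh, sort_keys=False)
    return cfg_path
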
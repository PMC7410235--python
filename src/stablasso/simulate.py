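"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure of a maternal-immune-activation (MIA)
mouse study: dams are assigned to an exposed (poly(I:C)-injected) or control
group, each dam contributes a litter of pups, and every pup carries

* dam-level parental covariates (shared by littermates),
* pup-level behavioural phenotypes,
* a correlated block of log-normal serum cytokines, left-censored at
  analyte-specific lower limits of detection (LLOD).

Exposure is drawn first at the dam level and variables are drawn
group-conditionally — the causal direction of the experiment — which induces
exactly the association that the downstream exposure-from-variables
regression is meant to detect.  Effects are specified as standardized mean
differences (exposed − control), on the log scale for cytokines.

Cytokine correlation uses a single shared latent factor: with loading c the
standardized log-concentration of analyte k in pup i is

    z_ik = d_k * exposed_i + c * F_i + sqrt(1 - c^2) * eps_ik,

so every pair of analytes has population correlation c^2.  Censoring targets
are met by placing each LLOD at the corresponding quantile of the analyte's
marginal (mixture-normal) population distribution, so the realized censored
fraction is binomial around the target.

All randomness flows from a master seed through named substreams (litters,
parental, behaviour, cytokines, missingness), so regenerating with one
component changed leaves the others untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .preprocess import CohortTable, VariableSpec

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "generate_cohort",
    "apply_censoring",
    "study_like_config",
    "write_truth",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


#: registry of non-cytokine variables: name -> (role, stage, units, level, loc, scale)
#: level is "dam" (shared within litter) or "pup"
VARIABLE_REGISTRY: dict[str, tuple[str, str, str, str, float, float]] = {
    "maternal_age": ("parental", "E0.5", "weeks", "dam", 20.0, 3.0),
    "paternal_age": ("parental", "E0.5", "weeks", "dam", 22.0, 4.0),
    "maternal_delta_mass": ("parental", "E13.5", "g", "dam", 0.5, 0.8),
    "maternal_delta_temp": ("parental", "E12.5", "degC", "dam", -0.2, 0.5),
    "body_mass_p15": ("pup", "P15", "g", "pup", 7.0, 0.8),
    "usv_count_p8": ("pup", "P8", "count", "pup", 300.0, 120.0),
    "distance_p13": ("pup", "P13", "m", "pup", 12.0, 4.0),
    "time_mobile_p13": ("pup", "P13", "s", "pup", 250.0, 80.0),
}

#: multiparity: dam-level Bernoulli binary, not group-shifted by default
MULTIPARITY_RATE = 0.4

STUDY_CYTOKINES = [
    "IFN-g", "IL-1b", "IL-5", "IL-6", "IL-15", "IL-16", "IL-17A", "IL-27p28",
    "IL-33", "CCL2", "CCL3", "CCL20", "CXCL1", "CXCL2", "CXCL10", "TNF-a",
]

_SUBSTREAMS = {"litters": 1, "parental": 2, "behaviour": 3, "cytokines": 4, "missing": 5}


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the cohort the analysis was designed for: 13 exposed vs
    8 control dams, litter means giving ~40 vs ~27 male pups, 16 cytokines
    with shared-factor correlation 0.55 on the log scale.
    """

    n_dams_exposed: int = 13
    n_dams_control: int = 8
    pups_per_litter_mean: tuple[float, float] = (3.1, 3.4)  # (exposed, control)
    behavioural_effects: dict[str, float] = field(default_factory=dict)
    cytokine_log_effects: dict[str, float] = field(default_factory=dict)
    cytokine_correlation: float = 0.55
    n_cytokines: int = 16
    cytokine_names: list[str] | None = None
    censored_analytes: dict[str, float] = field(default_factory=dict)
    missing_rate: float = 0.0
    seed: int = 0
    litter_sizes: tuple[list[int], list[int]] | None = None  # explicit override

    def __post_init__(self) -> None:
        if self.n_dams_exposed < 1 or self.n_dams_control < 1:
            raise ConfigError("dam counts must be >= 1")
        if not (0.0 <= self.cytokine_correlation < 1.0):
            raise ConfigError("cytokine_correlation must be in [0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must be in [0, 1)")
        if self.n_cytokines < 0:
            raise ConfigError("n_cytokines must be >= 0")
        if isinstance(self.pups_per_litter_mean, (int, float)):
            self.pups_per_litter_mean = (
                float(self.pups_per_litter_mean),
                float(self.pups_per_litter_mean),
            )
        if min(self.pups_per_litter_mean) < 1.0:
            raise ConfigError("pups_per_litter_mean must be >= 1")
        unknown = set(self.behavioural_effects) - set(VARIABLE_REGISTRY)
        if unknown:
            raise ConfigError(f"behavioural_effects reference unknown variables: {sorted(unknown)}")
        names = self.analyte_names()
        for src in (self.cytokine_log_effects, self.censored_analytes):
            unknown = set(src) - set(names)
            if unknown:
                raise ConfigError(f"unknown analytes: {sorted(unknown)}")
        for frac in self.censored_analytes.values():
            if not (0.0 <= frac <= 1.0):
                raise ConfigError("censoring targets must be in [0, 1]")
        if self.litter_sizes is not None:
            exp, ctl = self.litter_sizes
            if len(exp) != self.n_dams_exposed or len(ctl) != self.n_dams_control:
                raise ConfigError("explicit litter_sizes must match dam counts")
            if min(exp + ctl) < 1:
                raise ConfigError("litter sizes must be >= 1")

    def analyte_names(self) -> list[str]:
        if self.cytokine_names is not None:
            if len(self.cytokine_names) != self.n_cytokines:
                raise ConfigError("cytokine_names length must equal n_cytokines")
            return list(self.cytokine_names)
        return [f"CYT{k + 1:02d}" for k in range(self.n_cytokines)]


@dataclass
class SyntheticTruth:
    """Ground truth of one generated cohort, for parameter-recovery tests."""

    true_direction: dict[str, str]  # variable -> positive | negative | null
    true_log_effects: dict[str, float]
    realized_censoring: dict[str, float]


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, _SUBSTREAMS[stream]])


def _analyte_log_params(names: list[str]) -> dict[str, tuple[float, float]]:
    """Fixed per-analyte log-scale location/scale: typical pg/ml levels spread
    over ~3 orders of magnitude, log-SD 0.7."""
    return {
        name: (np.log(5.0) + 0.45 * (k % 8), 0.7) for k, name in enumerate(names)
    }


def generate_cohort(config: SimConfig) -> tuple[CohortTable, SyntheticTruth]:
    """Draw one cohort table plus its ground truth; deterministic given seed."""
    names = config.analyte_names()

    # --- litter structure -------------------------------------------------
    rng_lit = _rng(config.seed, "litters")
    if config.litter_sizes is not None:
        sizes_exp, sizes_ctl = (list(s) for s in config.litter_sizes)
    else:
        mu_e, mu_c = config.pups_per_litter_mean
        # truncated-at-1 Poisson: 1 + Poisson(mu - 1) has mean mu, min 1
        sizes_exp = (1 + rng_lit.poisson(mu_e - 1.0, config.n_dams_exposed)).tolist()
        sizes_ctl = (1 + rng_lit.poisson(mu_c - 1.0, config.n_dams_control)).tolist()

    dam_group = ["MIA"] * len(sizes_exp) + ["Control"] * len(sizes_ctl)
    dam_sizes = sizes_exp + sizes_ctl
    n_dams = len(dam_sizes)
    dam_of_pup = np.repeat(np.arange(n_dams), dam_sizes)
    n_pups = int(dam_of_pup.size)
    exposed_pup = np.array([dam_group[d] == "MIA" for d in dam_of_pup], dtype=float)

    data = pd.DataFrame(index=pd.Index([f"p{i + 1:03d}" for i in range(n_pups)],
                                       name="subject_id"))
    meta: dict[str, VariableSpec] = {}
    truth_dir: dict[str, str] = {}
    truth_eff: dict[str, float] = {}

    # --- dam-level parental variables ------------------------------------
    rng_par = _rng(config.seed, "parental")
    dam_exposed = np.array([g == "MIA" for g in dam_group], dtype=float)
    for name, (role, stage, units, level, loc, scale) in VARIABLE_REGISTRY.items():
        if level != "dam":
            continue
        eff = config.behavioural_effects.get(name, 0.0)
        z = eff * dam_exposed + rng_par.standard_normal(n_dams)
        data[name] = (loc + scale * z)[dam_of_pup]
        meta[name] = VariableSpec(name, role, stage=stage, units=units)
        truth_dir[name] = "positive" if eff > 0 else "negative" if eff < 0 else "null"
        truth_eff[name] = eff

    multi = rng_par.random(n_dams) < MULTIPARITY_RATE
    data["multiparity"] = np.where(multi[dam_of_pup], "Yes", "No")
    meta["multiparity"] = VariableSpec("multiparity", "parental", stage="E0.5", kind="binary")
    truth_dir["multiparity"] = "null"
    truth_eff["multiparity"] = 0.0

    # litter size is structural: the pup's own litter size
    data["litter_size"] = np.asarray(dam_sizes, dtype=float)[dam_of_pup]
    meta["litter_size"] = VariableSpec("litter_size", "pup", stage="P4", units="pups")
    mu_e, mu_c = config.pups_per_litter_mean
    struct_eff = float(np.sign(mu_e - mu_c))
    truth_dir["litter_size"] = (
        "positive" if struct_eff > 0 else "negative" if struct_eff < 0 else "null"
    )
    truth_eff["litter_size"] = struct_eff

    # --- pup-level behavioural variables ----------------------------------
    rng_beh = _rng(config.seed, "behaviour")
    for name, (role, stage, units, level, loc, scale) in VARIABLE_REGISTRY.items():
        if level != "pup":
            continue
        eff = config.behavioural_effects.get(name, 0.0)
        z = eff * exposed_pup + rng_beh.standard_normal(n_pups)
        data[name] = loc + scale * z
        meta[name] = VariableSpec(name, role, stage=stage, units=units)
        truth_dir[name] = "positive" if eff > 0 else "negative" if eff < 0 else "null"
        truth_eff[name] = eff

    # --- cytokines ---------------------------------------------------------
    rng_cyt = _rng(config.seed, "cytokines")
    c = config.cytokine_correlation
    log_params = _analyte_log_params(names)
    factor = rng_cyt.standard_normal(n_pups)
    noise = rng_cyt.standard_normal((n_pups, len(names)))
    w_e = sum(sizes_exp) / n_pups
    z_block = c * factor[:, None] + np.sqrt(1.0 - c * c) * noise
    censored = pd.DataFrame(False, index=data.index, columns=list(data.columns) + names)
    truth_cens: dict[str, float] = {}
    for k, name in enumerate(names):
        d_k = config.cytokine_log_effects.get(name, 0.0)
        m_k, s_k = log_params[name]
        z = d_k * exposed_pup + z_block[:, k]
        conc = np.exp(m_k + s_k * z)
        target = config.censored_analytes.get(name, 0.0)
        if target > 0.0:
            zq = _mixture_quantile(target, d_k, w_e)
            llod = float(np.exp(m_k + s_k * zq))
        else:
            llod = float(np.exp(m_k - 6.0 * s_k))  # far below the bulk
        data[name] = conc
        meta[name] = VariableSpec(name, "cytokine", stage="P15", units="pg/ml", llod=llod)
        truth_dir[name] = "positive" if d_k > 0 else "negative" if d_k < 0 else "null"
        truth_eff[name] = d_k

    data["group"] = [dam_group[d] for d in dam_of_pup]
    meta["group"] = VariableSpec("group", "outcome", kind="binary")

    censored = censored.reindex(columns=data.columns, fill_value=False)
    table = CohortTable(data, censored, meta, outcome="group")

    for name in names:
        llod = meta[name].llod
        table = apply_censoring(table, name, llod)
        truth_cens[name] = float(table.censored[name].mean())

    # --- missingness (MCAR over predictor cells) ---------------------------
    if config.missing_rate > 0.0:
        rng_mis = _rng(config.seed, "missing")
        predictors = table.predictors
        mask = rng_mis.random((n_pups, len(predictors))) < config.missing_rate
        for j, col in enumerate(predictors):
            rows = mask[:, j] & ~table.censored[col].to_numpy()
            if rows.any():
                if table.data[col].dtype == object:
                    table.data.loc[rows, col] = np.nan
                else:
                    table.data.loc[rows, col] = np.nan

    truth = SyntheticTruth(truth_dir, truth_eff, truth_cens)
    return table, truth


def _mixture_quantile(q: float, d: float, w_exposed: float) -> float:
    """Quantile of the two-group mixture normal w*N(d,1) + (1-w)*N(0,1)."""
    def cdf(z: float) -> float:
        return w_exposed * stats.norm.cdf(z - d) + (1 - w_exposed) * stats.norm.cdf(z)

    lo, hi = -10.0 + min(0.0, d), 10.0 + max(0.0, d)
    return float(optimize.brentq(lambda z: cdf(z) - q, lo, hi, xtol=1e-12))


def apply_censoring(table: CohortTable, analyte: str, llod: float) -> CohortTable:
    """Mark values strictly below ``llod`` as below-LLOD and record the LLOD."""
    if analyte not in table.data.columns:
        raise KeyError(f"unknown analyte {analyte!r}")
    if table.data[analyte].dtype == object:
        raise TypeError(f"analyte {analyte!r} is not numeric")
    table = table.copy()
    below = table.data[analyte] < llod
    table.censored[analyte] = below | table.censored[analyte]
    table.data.loc[below, analyte] = np.nan
    spec = table.meta[analyte]
    if spec.role == "cytokine" and llod > 0:
        table.meta[analyte] = VariableSpec(
            spec.name, spec.role, stage=spec.stage, kind=spec.kind,
            units=spec.units, llod=float(llod),
        )
    return table


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    rows = []
    for name, direction in truth.true_direction.items():
        rows.append(
            {
                "name": name,
                "direction": direction,
                "log_effect": truth.true_log_effects.get(name, 0.0),
                "realized_censoring": truth.realized_censoring.get(name, ""),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> SyntheticTruth:
    df = pd.read_csv(path, sep="\t")
    direction = dict(zip(df["name"], df["direction"]))
    eff = dict(zip(df["name"], df["log_effect"].astype(float)))
    cens = {
        r["name"]: float(r["realized_censoring"])
        for _, r in df.iterrows()
        if pd.notna(r["realized_censoring"]) and r["realized_censoring"] != ""
    }
    return SyntheticTruth(direction, eff, cens)


def study_like_config(
    seed: int = 0,
    missing_rate: float = 0.0,
    censored_analytes: dict[str, float] | None = None,
    exact_counts: bool = True,
) -> SimConfig:
    """A configuration emulating the MIA cohort the pipeline targets.

    13 exposed and 8 control dams; with ``exact_counts`` the litter sizes are
    fixed so the cohort has exactly 40 exposed and 27 control pups.  Effect
    sizes reproduce the direction pattern of the study's stable associations:
    reduced maternal mass/temperature response magnitude proxies, smaller
    litters, heavier and hypoactive pups with fewer vocalizations under MIA,
    raised TNF-a and IL-15, lowered IL-5 and CXCL10.
    """
    if censored_analytes is None:
        censored_analytes = {"IL-16": 0.15, "CCL20": 0.10}
    litters = None
    if exact_counts:
        # 13 litters summing to 40 and 8 litters summing to 27
        litters = ([4, 3, 3, 3, 3, 3, 3, 3, 3, 3, 3, 3, 3], [4, 4, 4, 3, 3, 3, 3, 3])
    return SimConfig(
        n_dams_exposed=13,
        n_dams_control=8,
        pups_per_litter_mean=(3.1, 3.4),
        litter_sizes=litters,
        behavioural_effects={
            "maternal_delta_mass": -1.4,
            "maternal_delta_temp": -1.1,
            "body_mass_p15": 1.2,
            "usv_count_p8": -1.1,
            "distance_p13": -0.8,
            "time_mobile_p13": -0.9,
        },
        cytokine_log_effects={
            "TNF-a": 1.0,
            "IL-15": 0.9,
            "IL-5": -0.9,
            "CXCL10": -0.9,
        },
        cytokine_correlation=0.55,
        n_cytokines=16,
        cytokine_names=list(STUDY_CYTOKINES),
        censored_analytes=censored_analytes,
        missing_rate=missing_rate,
        seed=seed,
    )
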
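"""Synthetic labeling-study generator with known ground truth.

Emulates the study design end to end: piecewise-exponential body-water
enrichment (6-week labeling for patients, 9-week for controls),
granulocyte saturation curves, subset enrichment following the kinetic
mixture with Gaussian noise on the arcsin-sqrt scale, exponentially
trending cell counts with Gaussian noise on the log10 scale, and qPCR
Ct values consistent with a configured division history. The
"study-design" cohort preset sets patient/control production-rate folds
of 6/3/8/4 for the T-cell subsets (2/3.5/5 for B-cells) and a naive-CD8
loss-rate fold of 9.5, against steady-state controls.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .labelmodel import (
    LYMPHOCYTE_SUBSETS,
    BodyWaterParams,
    KineticMixture,
    average_production_rate,
    body_water,
    granulocyte_max,
    mixture_label_fraction,
    mono_label_fraction,
)

__all__ = [
    "SubsetTruth",
    "NoiseConfig",
    "Schedule",
    "TruthConfig",
    "IndividualDataset",
    "CohortDataset",
    "patient_config",
    "control_config",
    "generate_individual",
    "generate_cohort",
    "STUDY_PRODUCTION_FOLDS",
    "STUDY_LOSS_FOLDS",
]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SubsetTruth:
    """Generating kinetics for one lymphocyte subset."""

    alphas: tuple[float, ...]
    rates: tuple[float, ...]
    d: float
    x0: float
    sigma: float | None = None  # explicit source mode (cells/ml/day)

    @property
    def p_avg(self) -> float:
        return float(np.dot(self.alphas, self.rates))


@dataclass(frozen=True)
class NoiseConfig:
    sd_enrichment: float = 0.02  # arcsin-sqrt scale
    sd_counts: float = 0.05  # log10 units
    sd_ct: float = 0.0  # qPCR cycles
    raw_scale: bool = False  # misspecified-noise mode: additive on raw scale


@dataclass(frozen=True)
class Schedule:
    tau: float = 42.0
    blood_days: tuple[float, ...] = (7, 14, 28, 42, 63, 91, 126, 182, 273, 364)
    urine_days: tuple[float, ...] = (1, 3, 7, 14, 21, 28, 35, 42, 49, 56, 70, 91)

    def __post_init__(self) -> None:
        labeling = [t for t in self.blood_days if t <= self.tau]
        if len(labeling) < 2:
            raise ConfigError("schedule needs >= 2 blood draws during labeling")


@dataclass(frozen=True)
class TruthConfig:
    """Every generating parameter for one individual."""

    body_water: BodyWaterParams
    p_gran: float
    c: float
    subsets: Mapping[str, SubsetTruth]
    leuk_intercept: float = 6.0e6  # cells/ml
    leuk_slope: float = 0.0  # cells/ml/day
    krec_divisions: float = 6.0
    trec_per_cell: float = 0.05
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    schedule: Schedule = field(default_factory=Schedule)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["subsets"] = {k: asdict(v) for k, v in self.subsets.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TruthConfig":
        d = dict(d)
        d["body_water"] = BodyWaterParams(**d["body_water"])
        d["subsets"] = {
            k: SubsetTruth(
                alphas=tuple(v["alphas"]), rates=tuple(v["rates"]),
                d=v["d"], x0=v["x0"], sigma=v.get("sigma"),
            )
            for k, v in d["subsets"].items()
        }
        d["noise"] = NoiseConfig(**d["noise"])
        sched = dict(d["schedule"])
        sched["blood_days"] = tuple(sched["blood_days"])
        sched["urine_days"] = tuple(sched["urine_days"])
        d["schedule"] = Schedule(**sched)
        return cls(**d)


@dataclass
class IndividualDataset:
    individual: str
    group: str
    enrichment: pd.DataFrame
    counts: pd.DataFrame
    qpcr: pd.DataFrame
    trec: pd.DataFrame
    truth: dict


@dataclass
class CohortDataset:
    enrichment: pd.DataFrame
    counts: pd.DataFrame
    qpcr: pd.DataFrame
    trec: pd.DataFrame
    groups: pd.DataFrame
    truth: dict[str, dict]


# ---------------------------------------------------------------------------
# presets

#: patient / healthy-control ratios of average per-cell production rates
STUDY_PRODUCTION_FOLDS = {
    "naive_cd4": 6.0,
    "memory_cd4": 3.0,
    "naive_cd8": 8.0,
    "memory_cd8": 4.0,
    "naive_b": 2.0,
    "switched_memory_b": 3.5,
    "igm_memory_b": 5.0,
}

#: patient / healthy-control ratios of loss rates
STUDY_LOSS_FOLDS = {
    "naive_cd4": 3.0,
    "memory_cd4": 3.0,
    "naive_cd8": 9.5,
    "memory_cd8": 4.0,
    "naive_b": 2.0,
    "switched_memory_b": 3.5,
    "igm_memory_b": 5.0,
}

_CONTROL_RATES = {
    "naive_cd4": 0.001,
    "memory_cd4": 0.008,
    "naive_cd8": 0.001,
    "memory_cd8": 0.008,
    "naive_b": 0.010,
    "switched_memory_b": 0.020,
    "igm_memory_b": 0.015,
}

_X0 = {
    "naive_cd4": 2.0e5,
    "memory_cd4": 1.5e5,
    "naive_cd8": 1.0e5,
    "memory_cd8": 1.0e5,
    "naive_b": 1.0e5,
    "switched_memory_b": 3.0e4,
    "igm_memory_b": 3.0e4,
}

_CONTROL_SCHEDULE = Schedule(
    tau=63.0,
    blood_days=(7, 21, 42, 63, 84, 112, 154, 210, 280, 364),
    urine_days=(1, 3, 7, 14, 21, 28, 42, 56, 63, 70, 84, 91),
)

_BW = dict(f=0.019, delta=0.065, beta=0.0075)


def control_config(noise: NoiseConfig | None = None) -> TruthConfig:
    """Healthy-control truth: steady state (d = p, flat counts), 9-week
    labeling."""
    subsets = {
        s: SubsetTruth(alphas=(1.0,), rates=(r,), d=r, x0=_X0[s])
        for s, r in _CONTROL_RATES.items()
    }
    return TruthConfig(
        body_water=BodyWaterParams(tau=63.0, **_BW),
        p_gran=0.35,
        c=4.2,
        subsets=subsets,
        krec_divisions=8.0,
        trec_per_cell=0.01,
        noise=noise or NoiseConfig(),
        schedule=_CONTROL_SCHEDULE,
    )


def patient_config(
    production_folds: Mapping[str, float] | None = None,
    loss_folds: Mapping[str, float] | None = None,
    noise: NoiseConfig | None = None,
) -> TruthConfig:
    """Patient truth: control rates scaled by the configured folds,
    6-week labeling, counts trending per the resulting net rate."""
    pf = dict(STUDY_PRODUCTION_FOLDS, **(production_folds or {}))
    lf = dict(STUDY_LOSS_FOLDS, **(loss_folds or {}))
    subsets = {}
    for s, r in _CONTROL_RATES.items():
        p = r * pf[s]
        d = r * lf[s]  # control d equals control p (steady state)
        subsets[s] = SubsetTruth(alphas=(1.0,), rates=(p,), d=d, x0=_X0[s] * 0.6)
    return TruthConfig(
        body_water=BodyWaterParams(tau=42.0, **_BW),
        p_gran=0.35,
        c=4.2,
        subsets=subsets,
        krec_divisions=6.0,
        trec_per_cell=0.05,
        noise=noise or NoiseConfig(),
        schedule=Schedule(),
    )


# ---------------------------------------------------------------------------
# generation


def _enrichment_noise(model, sd, rng, raw_scale=False):
    model = np.asarray(model, dtype=float)
    if sd == 0:
        return model.copy()
    if raw_scale:
        return np.maximum(model + rng.normal(0.0, sd, size=model.shape), 0.0)
    y = np.arcsin(np.sqrt(np.clip(model, 0.0, 1.0))) + rng.normal(
        0.0, sd, size=model.shape
    )
    return np.clip(np.sin(y) ** 2, 0.0, 1.0)


def _count_noise(model, sd, rng):
    model = np.asarray(model, dtype=float)
    if sd == 0:
        return model.copy()
    return 10.0 ** (np.log10(model) + rng.normal(0.0, sd, size=model.shape))


def _sigma_mode_enrichment(t, st: SubsetTruth, bw: BodyWaterParams, c: float):
    """Explicit-source simulation: dN/dt = sigma + (p_div - d) N,
    dL/dt = sigma c U + p_div c U N - d L; returns L/N at t."""
    p_div, d, sigma, n0 = st.rates[0], st.d, st.sigma, st.x0

    def rhs(tt, y):
        n, l = y
        u = body_water(tt, bw)
        return [
            sigma + (p_div - d) * n,
            sigma * c * u + p_div * c * u * n - d * l,
        ]

    t = np.asarray(t, dtype=float)
    sol = solve_ivp(
        rhs, (0.0, float(t.max())), [n0, 0.0], t_eval=t,
        rtol=1e-10, atol=1e-12, method="LSODA",
    )
    return sol.y[1] / sol.y[0]


def generate_individual(
    cfg: TruthConfig,
    seed: int,
    individual: str = "P1",
    group: str = "patient",
) -> IndividualDataset:
    """Generate one individual's full dataset (urine, granulocyte and
    subset enrichment, counts, qPCR) plus the truth record.

    Deterministic given ``seed``. Enrichment observations are
    ``clip01(sin^2(arcsin(sqrt(model)) + eps))`` with Gaussian ``eps``;
    counts are ``10^(log10(model) + eta)``.
    """
    rng = np.random.default_rng(seed)
    bw, sched, noise = cfg.body_water, cfg.schedule, cfg.noise
    t_blood = np.asarray(sched.blood_days, dtype=float)
    t_urine = np.asarray(sched.urine_days, dtype=float)

    rows = []
    u = body_water(t_urine, bw)
    for t, v in zip(t_urine, _enrichment_noise(u, noise.sd_enrichment, rng,
                                               noise.raw_scale)):
        rows.append((individual, "urine", t, v, False))
    g = mono_label_fraction(t_blood, cfg.p_gran, bw, cfg.c)
    for t, v in zip(t_blood, _enrichment_noise(g, noise.sd_enrichment, rng,
                                               noise.raw_scale)):
        rows.append((individual, "granulocytes", t, v, False))
    # subset enrichment is analyzed after scaling to the granulocyte
    # maximum, so subset noise lives on the arcsin-sqrt of the *scaled*
    # values (the transform the fitter assumes homoscedastic)
    m_scale = granulocyte_max(
        lambda tt: mono_label_fraction(tt, cfg.p_gran, bw, cfg.c), t_blood
    )
    for s, st in cfg.subsets.items():
        if st.sigma is not None:
            model = _sigma_mode_enrichment(t_blood, st, bw, cfg.c)
        else:
            mix = KineticMixture(st.alphas, st.rates, c=cfg.c)
            model = mixture_label_fraction(t_blood, mix, bw)
        scaled = _enrichment_noise(model / m_scale, noise.sd_enrichment, rng,
                                   noise.raw_scale)
        for t, v in zip(t_blood, scaled * m_scale):
            rows.append((individual, s, t, v, False))
    enrichment = pd.DataFrame(
        rows,
        columns=["individual", "compartment", "time_days", "enrichment",
                 "scaled_flag"],
    )

    leuk_model = cfg.leuk_intercept + cfg.leuk_slope * t_blood
    leuk_obs = _count_noise(leuk_model, noise.sd_counts, rng)
    count_rows = []
    for s, st in cfg.subsets.items():
        x_model = st.x0 * np.exp((st.p_avg - st.d) * t_blood)
        x_obs = _count_noise(x_model, noise.sd_counts, rng)
        for t, leuk, x in zip(t_blood, leuk_obs, x_obs):
            count_rows.append((individual, t, leuk, s, x, x / leuk))
    counts = pd.DataFrame(
        count_rows,
        columns=["individual", "time_days", "leukocytes_per_ml", "subset",
                 "subset_count_per_ml", "fraction"],
    )

    # KREC assay: coding joints double per division, signal joints do not,
    # so Ct_signal - Ct_coding grows by one cycle per division.
    ctrl = {"ct_signal_joint": 24.0, "ct_coding_joint": 24.0, "ct_albumin": 22.0}
    samp = {
        "ct_coding_joint": 25.0,
        "ct_signal_joint": 25.0 + cfg.krec_divisions,
        "ct_albumin": 23.0,
    }
    qpcr_rows = []
    for target in ("signal", "coding", "albumin"):
        key = {"signal": "ct_signal_joint", "coding": "ct_coding_joint",
               "albumin": "ct_albumin"}[target]
        qpcr_rows.append(("U698-DB01", "naive_b", target, ctrl[key], True))
        ct = samp[key] + (rng.normal(0.0, noise.sd_ct) if noise.sd_ct else 0.0)
        qpcr_rows.append((individual, "naive_b", target, ct, False))
    qpcr = pd.DataFrame(
        qpcr_rows,
        columns=["individual", "subset", "target", "ct_mean", "control_flag"],
    )

    cells_in = 1.0e5
    trec = pd.DataFrame(
        [
            (individual, s, cfg.trec_per_cell * cells_in, cells_in)
            for s in ("naive_cd4", "naive_cd8")
            if s in cfg.subsets
        ],
        columns=["individual", "subset", "trec_copies", "cell_equivalents"],
    )

    truth = {"individual": individual, "group": group, "seed": seed,
             "config": cfg.to_dict()}
    return IndividualDataset(individual, group, enrichment, counts, qpcr,
                             trec, truth)


def _jittered(cfg: TruthConfig, rng: np.random.Generator, jitter: float) -> TruthConfig:
    """Per-individual biological variation: lognormal factors on rates,
    body-water parameters and counts."""
    if jitter == 0:
        return cfg
    j = lambda sd=jitter: float(np.exp(rng.normal(0.0, sd)))
    bw = cfg.body_water
    bw2 = BodyWaterParams(
        f=min(bw.f * j(), 0.08), delta=bw.delta * j(), beta=min(bw.beta * j(), 0.05),
        tau=bw.tau, t0=bw.t0,
    )
    subsets = {}
    for s, st in cfg.subsets.items():
        jr = j()
        rates = tuple(r * jr for r in st.rates)
        # jitter production but keep the template's net growth rate:
        # independently jittered (p, d) would let counts of fast subsets
        # drift exponentially beyond the leukocyte total within a year
        net = st.p_avg - st.d
        p_new = float(np.dot(st.alphas, rates))
        subsets[s] = replace(
            st, rates=rates, d=max(p_new - net, 0.0), x0=st.x0 * j(2 * jitter)
        )
    return replace(
        cfg,
        body_water=bw2,
        p_gran=cfg.p_gran * j(),
        c=cfg.c * j(jitter / 2),
        subsets=subsets,
        leuk_intercept=cfg.leuk_intercept * j(),
    )


def generate_cohort(
    n_patients: int = 6,
    n_controls: int = 10,
    seed: int = 0,
    patient_cfg: TruthConfig | None = None,
    control_cfg: TruthConfig | None = None,
    jitter: float = 0.05,
) -> CohortDataset:
    """Generate a full cohort (study-design preset by default): patients
    with elevated production/loss folds versus steady-state controls."""
    if n_patients < 1 or n_controls < 1:
        raise ConfigError("need at least one individual per group")
    patient_cfg = patient_cfg or patient_config()
    control_cfg = control_cfg or control_config(noise=patient_cfg.noise)
    rng = np.random.default_rng(seed)

    datasets = []
    for i in range(n_patients):
        cfg = _jittered(patient_cfg, rng, jitter)
        datasets.append(
            generate_individual(cfg, int(rng.integers(2**31)), f"PT{i + 1:02d}",
                                "patient")
        )
    for i in range(n_controls):
        cfg = _jittered(control_cfg, rng, jitter)
        datasets.append(
            generate_individual(cfg, int(rng.integers(2**31)), f"HC{i + 1:02d}",
                                "healthy_control")
        )

    groups = pd.DataFrame(
        [(d.individual, d.group) for d in datasets],
        columns=["individual", "group"],
    )
    # the control-line qPCR rows repeat per individual; keep one copy
    qpcr = pd.concat([d.qpcr for d in datasets], ignore_index=True)
    qpcr = qpcr[~(qpcr["control_flag"] & qpcr.duplicated(
        subset=["individual", "subset", "target"]))].reset_index(drop=True)
    return CohortDataset(
        enrichment=pd.concat([d.enrichment for d in datasets], ignore_index=True),
        counts=pd.concat([d.counts for d in datasets], ignore_index=True),
        qpcr=qpcr,
        trec=pd.concat([d.trec for d in datasets], ignore_index=True),
        groups=groups,
        truth={d.individual: d.truth for d in datasets},
    )
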
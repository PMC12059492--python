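"""Synthetic EMR cohort simulator with known ground truth.

The generator emulates the structural features of large ICU event-stream
databases that the pipeline assumes, without claiming physiological realism:

* a latent per-stay deterioration process (discrete-time AR(1), shared across
  variables plus a per-variable component);
* numeric variables that are affine functions of their latent driver plus
  observation noise, sampled at irregular, per-variable rates (inhomogeneous
  Poisson observation times, i.e. exponential inter-arrival gaps);
* categorical variables obtained by thresholding their latent driver;
* partly informative missingness — the sampling rate rises with latent
  severity, so the observation mask itself carries signal;
* a logistic per-hour death hazard driven by a designated subset of causal
  variables, with the intercept calibrated to a target in-hospital mortality;
* deaths that may be deferred past ICU discharge (post-ICU in-hospital
  death), multi-stay patients, and heavy class imbalance.

Everything is a pure function of :class:`SimConfig` (including its seed), so
identical configs produce byte-identical cohort files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from tbal.data_model import Cohort, VariableSpec

SEX_LEVELS = ("female", "male")
RACE_LEVELS = ("asian", "black", "hispanic", "white", "other")
RACE_PROBS = (0.02, 0.12, 0.04, 0.72, 0.10)
CAT_LEVELS = ("low", "mid", "high")


def make_fixture_dictionary(n_numeric: int, n_categorical: int
                            ) -> list[VariableSpec]:
    """Build a reduced variable dictionary mirroring typical clinical roles.

    Numeric variables aggregate by in-bin median and impute interior gaps by
    linear interpolation (head gaps carry the earliest observation, tails
    carry the last).  Categorical variables aggregate by mode and use
    last-observation-carried-forward semantics with an explicit ``"missing"``
    category appended.
    """
    specs: list[VariableSpec] = []
    for i in range(n_numeric):
        specs.append(VariableSpec(
            name=f"num_{i:02d}", vtype="numeric",
            aggregation="median", imputation="linear",
        ))
    for i in range(n_categorical):
        specs.append(VariableSpec(
            name=f"cat_{i:02d}", vtype="categorical",
            aggregation="mode", imputation="locf",
            categories=CAT_LEVELS + ("missing",),
        ))
    return specs


@dataclass(frozen=True)
class SimConfig:
    """Generative-model parameters for one synthetic cohort.

    The defaults are the package's reference study conditions: roughly 2,000
    stays (1,850 patients with an 8% second-stay probability), 20 variables
    of which the first three numerics drive the hazard, an in-hospital
    mortality target of 8.5%, and stay lengths whose log-normal distribution
    (median 60 h, clipped to ``los_range_h``) yields next-24-hour positive
    timepoint prevalence near 2–3%.
    """

    n_patients: int = 1850
    multi_stay_prob: float = 0.08
    n_numeric_vars: int = 17
    n_categorical_vars: int = 3
    #: per-variable mean inter-observation gap drawn uniformly from this range
    sampling_rate_h: tuple[float, float] = (1.0, 6.0)
    causal_vars: tuple[str, ...] = ("num_00", "num_01", "num_02")
    #: per-causal-variable log-hazard coefficients (per SD of latent driver)
    effect_sizes: tuple[float, ...] = (2.0, 1.6, 1.2)
    #: per-hour death probability at zero latent severity; used directly when
    #: target_mortality is None, otherwise only as the bisection starting point
    baseline_hazard: float = 8e-4
    #: calibrate the hazard intercept so expected in-hospital mortality hits
    #: this fraction; None disables calibration
    target_mortality: float | None = 0.085
    los_range_h: tuple[float, float] = (16.0, 400.0)
    seed: int = 0

    # latent-process shape parameters
    ar_rho: float = 0.97           # hourly AR(1) autocorrelation
    shared_weight: float = 0.6     # variance share of the stay-level severity
    obs_noise: float = 0.3         # observation noise, in latent SD units
    informative_sampling: float = 0.3   # log-rate increase per unit severity
    post_icu_death_prob: float = 0.25   # death deferred past ICU discharge
    post_icu_death_mean_h: float = 48.0
    los_log_sigma: float = 0.7
    #: additive mean shift (in SD units) applied to every numeric variable's
    #: observed values — used to construct covariate-shifted transfer cohorts
    feature_shift: float = 0.0

    def var_names(self) -> list[str]:
        return [f"num_{i:02d}" for i in range(self.n_numeric_vars)] + \
               [f"cat_{i:02d}" for i in range(self.n_categorical_vars)]

    def __post_init__(self) -> None:
        if not 0.0 <= self.multi_stay_prob <= 1.0:
            raise ValueError("multi_stay_prob must be in [0, 1]")
        if len(self.effect_sizes) != len(self.causal_vars):
            raise ValueError("effect_sizes and causal_vars must align")
        unknown = set(self.causal_vars) - set(self.var_names())
        if unknown:
            raise ValueError(f"causal_vars not generated: {sorted(unknown)}")


@dataclass
class GroundTruth:
    """What the simulator knows and the pipeline must rediscover."""

    stays: pd.DataFrame            # stay_id, patient_id, died, death_time_h, ...
    variables: tuple[str, ...]
    causal_vars: tuple[str, ...]
    effect_sizes: tuple[float, ...]
    hazard_intercept: float        # calibrated logit of the per-hour hazard
    achieved_mortality: float
    #: per-stay hourly hazard-driver series (sum of effect * latent driver)
    hazard_driver: dict[str, np.ndarray] = field(default_factory=dict)


def _ar1(rng: np.random.Generator, n: int, rho: float, size: int = 1
         ) -> np.ndarray:
    """Stationary AR(1) paths, shape (size, n), unit marginal variance."""
    x = np.empty((size, n))
    x[:, 0] = rng.standard_normal(size)
    innov_sd = np.sqrt(1.0 - rho * rho)
    eps = rng.standard_normal((size, n - 1)) if n > 1 else None
    for t in range(1, n):
        x[:, t] = rho * x[:, t - 1] + innov_sd * eps[:, t - 1]
    return x


def simulate_cohort(config: SimConfig) -> tuple[Cohort, GroundTruth]:
    """Simulate one cohort; same config (incl. seed) gives identical output."""
    rng = np.random.default_rng(config.seed)
    var_names = config.var_names()
    n_num = config.n_numeric_vars
    causal_idx = [var_names.index(v) for v in config.causal_vars]
    betas = np.asarray(config.effect_sizes, dtype=float)
    w = config.shared_weight

    # cohort-level variable scales and sampling rates
    mu = rng.uniform(20.0, 150.0, size=n_num)
    sigma = rng.uniform(1.0, 15.0, size=n_num)
    mean_gap = rng.uniform(*config.sampling_rate_h, size=len(var_names))

    # ----- patients and stays ------------------------------------------------
    patients = []
    for i in range(config.n_patients):
        pid = f"p{i:05d}"
        age = int(np.clip(round(rng.normal(59.0, 15.0)), 18, 80))
        sex = SEX_LEVELS[int(rng.random() < 0.56)]
        race = RACE_LEVELS[rng.choice(len(RACE_LEVELS), p=RACE_PROBS)]
        n_stays = 2 if rng.random() < config.multi_stay_prob else 1
        patients.append((pid, age, sex, race, n_stays))

    # ----- pass 1: latent trajectories + death uniforms ----------------------
    lo, hi = config.los_range_h
    stay_rows = []
    latents = []       # per stay: (planned_T, shared s, per-var z, death unifs)
    sidx = 0
    for pid, age, sex, race, n_stays in patients:
        for _ in range(n_stays):
            stay_id = f"s{sidx:05d}"
            sidx += 1
            planned_los = float(np.clip(
                np.exp(rng.normal(np.log(60.0), config.los_log_sigma)), lo, hi))
            T = int(np.floor(planned_los)) + 1
            s = _ar1(rng, T, config.ar_rho)[0]
            u = _ar1(rng, T, config.ar_rho, size=len(var_names))
            z = np.sqrt(w) * s[None, :] + np.sqrt(1.0 - w) * u   # (D, T)
            death_unif = rng.random(T)
            driver = betas @ z[causal_idx, :]                    # (T,)
            latents.append((stay_id, pid, age, sex, race, planned_los,
                            T, s, z, death_unif, driver))

    # ----- hazard intercept --------------------------------------------------
    drivers = [lat[10] for lat in latents]
    if config.target_mortality is None:
        p0 = float(np.clip(config.baseline_hazard, 1e-10, 1 - 1e-10))
        b = float(np.log(p0 / (1.0 - p0)))
    else:
        b = _calibrate_intercept(drivers, config.target_mortality,
                                 np.log(config.baseline_hazard /
                                        (1 - config.baseline_hazard)))

    # ----- pass 2: deaths, events --------------------------------------------
    def sigmoid(x: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-x))

    ev_stay, ev_time, ev_var, ev_val = [], [], [], []
    truth_rows = []
    hazard_driver = {}
    n_died = 0
    for (stay_id, pid, age, sex, race, planned_los, T, s, z, death_unif,
         driver) in latents:
        p_death = sigmoid(b + driver)
        p_death[0] = 0.0                       # no death in the admission hour
        hit = np.flatnonzero(death_unif < p_death)
        died = hit.size > 0
        post_icu = False
        if died:
            tau = int(hit[0])
            frac = float(rng.random())
            if rng.random() < config.post_icu_death_prob:
                post_icu = True
                icu_los = tau + frac
                death_time = icu_los + float(
                    rng.exponential(config.post_icu_death_mean_h))
            else:
                death_time = tau + frac
                icu_los = death_time
            n_died += 1
        else:
            death_time = np.nan
            icu_los = planned_los

        T_obs = int(np.floor(icu_los)) + 1      # hours with any presence
        sev = np.clip(s[:T_obs], 0.0, 3.0)
        for d, name in enumerate(var_names):
            lam = np.exp(config.informative_sampling * sev) / mean_gap[d]
            counts = rng.poisson(lam)
            total = int(counts.sum())
            if total == 0:
                continue
            hours = np.repeat(np.arange(T_obs), counts)
            times = hours + rng.random(total)
            keep = times <= icu_los
            times, hours = times[keep], hours[keep]
            if times.size == 0:
                continue
            zvals = z[d, hours] + config.obs_noise * rng.standard_normal(
                times.size)
            if d < n_num:
                vals = mu[d] + sigma[d] * (zvals + config.feature_shift)
                vals = np.round(vals, 3)
                ev_val.extend(vals.tolist())
            else:
                labels = np.where(zvals < -0.8, "low",
                                  np.where(zvals > 0.8, "high", "mid"))
                ev_val.extend(labels.tolist())
            ev_stay.extend([stay_id] * times.size)
            ev_time.extend(np.round(times, 3).tolist())
            ev_var.extend([name] * times.size)

        stay_rows.append({
            "stay_id": stay_id, "patient_id": pid,
            "icu_los_h": round(float(icu_los), 3),
            "death_time_h": (round(float(death_time), 3) if died else np.nan),
            "age_years": age, "sex": sex, "race": race,
        })
        truth_rows.append({
            "stay_id": stay_id, "patient_id": pid, "died": died,
            "death_time_h": (round(float(death_time), 3) if died else np.nan),
            "icu_los_h": round(float(icu_los), 3),
            "post_icu_death": post_icu,
            "planned_los_h": round(planned_los, 3),
        })
        hazard_driver[stay_id] = driver

    stays = pd.DataFrame(stay_rows)
    events = pd.DataFrame({
        "stay_id": ev_stay, "time_h": ev_time,
        "variable": ev_var, "value": ev_val,
    }).sort_values(["stay_id", "time_h", "variable"],
                   kind="mergesort").reset_index(drop=True)

    dictionary = {s.name: s for s in make_fixture_dictionary(
        config.n_numeric_vars, config.n_categorical_vars)}
    cohort = Cohort(stays=stays, events=events, dictionary=dictionary)
    cohort.validate()

    achieved = n_died / max(len(stay_rows), 1)
    if (config.target_mortality is not None and config.target_mortality > 0
            and abs(achieved - config.target_mortality)
            > 0.5 * config.target_mortality):
        warnings.warn(
            f"target mortality {config.target_mortality:.3f} not reached; "
            f"achieved {achieved:.3f}", stacklevel=2)

    truth = GroundTruth(
        stays=pd.DataFrame(truth_rows),
        variables=tuple(var_names),
        causal_vars=config.causal_vars,
        effect_sizes=config.effect_sizes,
        hazard_intercept=b,
        achieved_mortality=achieved,
        hazard_driver=hazard_driver,
    )
    return cohort, truth


def _calibrate_intercept(drivers: Sequence[np.ndarray], target: float,
                         b0: float) -> float:
    """Bisect the hazard intercept so expected mortality matches ``target``.

    Expected mortality given the latent paths is
    ``mean_stays[1 - prod_t (1 - sigmoid(b + driver_t))]`` over hours 1..T-1,
    which is monotone increasing in ``b``.
    """
    def expected(bb: float) -> float:
        tot = 0.0
        for drv in drivers:
            p = 1.0 / (1.0 + np.exp(-(bb + drv[1:])))
            tot += 1.0 - np.exp(np.sum(np.log1p(-np.clip(p, 0, 1 - 1e-12))))
        return tot / len(drivers)

    lo_b, hi_b = -25.0, 5.0
    if expected(hi_b) < target:
        warnings.warn(
            f"target mortality {target} infeasible; max achievable "
            f"{expected(hi_b):.3f}", stacklevel=2)
        return hi_b
    for _ in range(60):
        mid = 0.5 * (lo_b + hi_b)
        if expected(mid) < target:
            lo_b = mid
        else:
            hi_b = mid
    return 0.5 * (lo_b + hi_b)


def write_ground_truth(truth: GroundTruth, stays_path: str | Path,
                       vars_path: str | Path) -> None:
    """Write per-stay event times and per-variable causal flags as CSV."""
    truth.stays.to_csv(stays_path, index=False)
    effect = dict(zip(truth.causal_vars, truth.effect_sizes))
    rows = [
        {"variable": name, "causal": name in effect,
         "effect_size": effect.get(name, 0.0)}
        for name in truth.variables
    ]
    pd.DataFrame(rows).to_csv(vars_path, index=False)
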
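"""Seeded synthetic cohorts of children's mental-health service use.

Emulates the statistical structure of an administrative visit registry:
five latent service-use classes (Minimal, Acute, Brief Episodic, Intensive,
Ongoing/Intensive-Episodic) with class-specific 48-month visit-probability
profiles, per-class visit volumes, class-conditional intake covariates
(four T-scored scales), demographics, and non-random covariate missingness.

The default configuration is calibrated once to published descriptives of a
multi-agency community registry: class prevalences 53.2/20.1/7.9/13.0/5.8 %,
profile anchors (Ongoing month 11 = 0.63; Intensive month 21 = 0.22; Brief
Episodic month 21 = 0.08), mean four-year visit counts 3.1/15.6/28.6/32.6/
86.7, class-conditional T-score means/SDs, 62.3 % male, and per-scale
missingness between 0.3 % and 12.4 %.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CLASS_NAMES",
    "SCALES",
    "GeneratorConfig",
    "SimulatedCohort",
    "default_config",
    "default_profiles",
    "sample_cohort",
    "inject_missingness",
    "month_edges",
]

#: Canonical class order used throughout: index 0..4.
CLASS_NAMES = (
    "Minimal",
    "Acute",
    "Brief Episodic",
    "Intensive",
    "Ongoing/Intensive-Episodic",
)

#: Covariate scale column names (T-score units).
SCALES = ("ext_t", "int_t", "imp_t", "burden_t")

N_MONTHS = 48
_MAX_EXTRA_VISITS = 19  # visits per active month capped at 1 + 19 = 20


def month_edges(n_months: int = N_MONTHS) -> np.ndarray:
    """Day-offset edges of the fixed-width month bins.

    Month m (1-based) covers day offsets [edges[m-1], edges[m]) from the
    index date; bins are 365.25/12 days wide, rounded to whole days.
    """
    return np.round(np.arange(n_months + 1) * 365.25 / 12.0).astype(np.int64)


def _segments(*pairs: tuple[int, float]) -> np.ndarray:
    """Build a 48-vector from (last_month, value) piecewise-constant runs."""
    out = np.empty(N_MONTHS)
    start = 0
    for last_month, value in pairs:
        out[start:last_month] = value
        start = last_month
    if start != N_MONTHS:
        raise ValueError("segments must cover exactly 48 months")
    return out


def default_profiles() -> np.ndarray:
    """Calibrated per-class monthly visit-probability curves (5 x 48).

    Piecewise-constant shapes satisfying the published anchors: every class
    has probability 1 in month 1 (the index visit defines month 1); the
    Ongoing class holds 0.63 through month 24 (anchor at month 11); the
    Intensive class decays through 0.22 at month 21; the Brief Episodic
    class shows two activity bumps separated by a 14-month near-zero span,
    with 0.08 at month 21 on the shoulder of the second bump.
    """
    # Late-tail rates are set in closed form from the published share of
    # children still in contact after 2 years: per-month q solves
    # 1 - (1-q)^24 = that share.
    minimal = _segments((1, 1.0), (2, 0.45), (3, 0.25), (4, 0.12),
                        (5, 0.05), (6, 0.02), (12, 0.01), (24, 0.003),
                        (48, 0.003))
    acute = _segments((1, 1.0), (2, 0.85), (3, 0.80), (4, 0.72), (5, 0.62),
                      (6, 0.50), (7, 0.38), (8, 0.26), (9, 0.16), (10, 0.09),
                      (11, 0.04), (12, 0.02), (24, 0.008), (48, 0.0036))
    brief = _segments((1, 1.0), (2, 0.60), (3, 0.45), (4, 0.30), (5, 0.15),
                      (6, 0.06), (20, 0.02), (25, 0.08), (34, 0.55),
                      (35, 0.40), (36, 0.25), (37, 0.12), (38, 0.05),
                      (48, 0.02))
    intensive = _segments((1, 1.0), (10, 0.75), (14, 0.58), (18, 0.42),
                          (19, 0.30), (20, 0.26), (21, 0.22), (22, 0.16),
                          (23, 0.12), (24, 0.08), (30, 0.04), (48, 0.008))
    ongoing = _segments((1, 1.0), (24, 0.63), (36, 0.50), (44, 0.35),
                        (48, 0.18))
    return np.vstack([minimal, acute, brief, intensive, ongoing])


# Table-derived per-class targets for mean total visits over 48 months.
_TARGET_VISITS = np.array([3.1, 15.6, 28.6, 32.6, 86.7])


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of the synthetic cohort generator.

    All per-class arrays follow the canonical order of :data:`CLASS_NAMES`.
    """

    n_children: int = 5000
    class_weights: tuple[float, ...] = (0.532, 0.201, 0.079, 0.130, 0.058)
    monthly_profiles: np.ndarray = field(default_factory=default_profiles)
    #: Poisson rate of extra visits per active month (visits = 1 + count).
    visits_per_active_month_rate: tuple[float, ...] = ()
    covariate_means: np.ndarray = field(default_factory=lambda: np.array([
        [65.5, 62.0, 63.4, 70.7],
        [69.4, 63.8, 66.8, 76.7],
        [69.6, 63.0, 66.6, 77.0],
        [70.9, 64.5, 68.6, 79.2],
        [72.5, 66.2, 71.0, 81.5],
    ]))
    covariate_sds: np.ndarray = field(default_factory=lambda: np.array([
        [13.3, 14.0, 13.8, 19.3],
        [12.9, 14.4, 13.9, 21.5],
        [12.0, 14.3, 14.8, 20.6],
        [13.1, 14.4, 15.2, 21.6],
        [13.0, 15.3, 15.2, 23.3],
    ]))
    covariate_correlation: float = 0.4
    sex_male_prob: tuple[float, ...] = (0.615, 0.609, 0.622, 0.678, 0.612)
    #: Marginal distribution of integer age (years 5..13) at the index visit.
    age_year_probs: tuple[float, ...] = tuple(
        np.array([8, 10, 9, 11, 12, 12, 12, 13, 14]) / 101.0)
    missing_rates: tuple[float, ...] = (0.003, 0.03, 0.08, 0.124)
    missing_mechanism: str = "MAR-on-Externalizing"
    #: Logistic slope of missingness on the standardized Externalizing score
    #: (MAR mechanism only; applies to the three non-Externalizing scales).
    mar_slope: float = 1.0
    intake_start: str = "2004-01-01"
    intake_end: str = "2006-12-31"
    seed: int = 0

    def __post_init__(self):
        w = np.asarray(self.class_weights, float)
        if abs(w.sum() - 1.0) > 1e-9 or (w < 0).any():
            raise ValueError("class_weights must be a probability vector")
        prof = np.asarray(self.monthly_profiles, float)
        if prof.shape != (len(w), N_MONTHS):
            raise ValueError(f"monthly_profiles must be {len(w)} x {N_MONTHS}")
        if (prof < 0).any() or (prof > 1).any():
            raise ValueError("monthly_profiles entries must lie in [0, 1]")
        if not np.allclose(prof[:, 0], 1.0):
            raise ValueError("month-1 profile entry must be 1 for every class"
                             " (the index visit defines month 1)")
        if not self.visits_per_active_month_rate:
            # Closed-form calibration: expected total visits over 48 months
            # is sum(profile) * (1 + rate), so rate = target/sum - 1.
            rates = np.maximum(_TARGET_VISITS / prof.sum(axis=1) - 1.0, 0.0)
            object.__setattr__(self, "visits_per_active_month_rate",
                               tuple(rates))
        if (np.asarray(self.visits_per_active_month_rate) < 0).any():
            raise ValueError("visit rates must be non-negative")
        if (np.asarray(self.covariate_sds) <= 0).any():
            raise ValueError("covariate_sds must be strictly positive")
        ap = np.asarray(self.age_year_probs, float)
        if abs(ap.sum() - 1.0) > 1e-9:
            raise ValueError("age_year_probs must sum to 1")
        if not 0 <= self.covariate_correlation < 1:
            raise ValueError("covariate_correlation must lie in [0, 1)")
        mr = np.asarray(self.missing_rates, float)
        if (mr < 0).any() or (mr > 1).any():
            raise ValueError("missing_rates must lie in [0, 1]")
        if self.missing_mechanism not in ("MCAR", "MAR-on-Externalizing"):
            raise ValueError("unknown missing_mechanism "
                             f"{self.missing_mechanism!r}")

    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SimulatedCohort:
    """Generated tables: one row per visit / child / child-covariate."""

    visits: pd.DataFrame      # child_id, visit_date, contact_mode, program_tag
    children: pd.DataFrame    # child_id, dob, sex, pdd_flag
    covariates: pd.DataFrame  # child_id, age_at_index, sex, ext_t..burden_t
    true_labels: pd.Series    # child_id -> class index 0..4

    def write(self, outdir) -> None:
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.visits.to_csv(outdir / "visits.csv", index=False)
        self.children.to_csv(outdir / "children.csv", index=False)
        self.covariates.to_csv(outdir / "covariates.csv", index=False)
        self.true_labels.rename("true_class").to_csv(
            outdir / "labels.csv", index_label="child_id")


def default_config(**overrides) -> GeneratorConfig:
    """The calibrated default generator configuration."""
    return GeneratorConfig(**overrides)


def sample_cohort(config: GeneratorConfig, seed: int | None = None
                  ) -> SimulatedCohort:
    """Draw a full synthetic cohort; identical (config, seed) pairs give
    identical tables.

    Per child: a latent class from ``class_weights``; an index date uniform
    in the intake window; for each of 48 month bins an active indicator from
    the class profile (month 1 is the index visit and always active); for
    each active month ``1 + min(Poisson(rate), 19)`` face-to-face visits on
    uniform days within the bin; sex, an integer age-year plus uniform
    fraction, and the four T-scores from the class-conditional multivariate
    normal with exchangeable correlation.
    """
    if config.n_children <= 0:
        raise ValueError("n_children must be positive")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_children
    k = len(config.class_weights)
    labels = rng.choice(k, size=n, p=np.asarray(config.class_weights))

    start = np.datetime64(config.intake_start)
    end = np.datetime64(config.intake_end)
    window_days = (end - start).astype(int) + 1
    index_dates = start + rng.integers(0, window_days, size=n).astype(
        "timedelta64[D]")

    prof = np.asarray(config.monthly_profiles)[labels]        # n x 48
    active = rng.random((n, N_MONTHS)) < prof
    active[:, 0] = True
    rates = np.asarray(config.visits_per_active_month_rate)[labels]
    extra = np.minimum(
        rng.poisson(np.broadcast_to(rates[:, None], (n, N_MONTHS))),
        _MAX_EXTRA_VISITS)
    counts = np.where(active, 1 + extra, 0)
    # Month 1's guaranteed visit is the index visit itself, pinned to day 0.
    counts[:, 0] -= 1

    edges = month_edges()
    child_idx, month_idx = np.nonzero(counts)
    reps = counts[child_idx, month_idx]
    child_rep = np.repeat(child_idx, reps)
    month_rep = np.repeat(month_idx, reps)
    lo, hi = edges[month_rep], edges[month_rep + 1]
    # Month-1 extras land on days 1..edges[1]-1 so day 0 stays unique.
    lo = np.where(month_rep == 0, 1, lo)
    days = lo + np.floor(rng.random(lo.size) * (hi - lo)).astype(np.int64)

    all_children = np.concatenate([np.arange(n), child_rep])
    all_days = np.concatenate([np.zeros(n, np.int64), days])
    visit_dates = index_dates[all_children] + all_days.astype("timedelta64[D]")
    visits = pd.DataFrame({
        "child_id": all_children,
        "visit_date": visit_dates,
        "contact_mode": "face_to_face",
        "program_tag": "cymhs",
    }).sort_values(["child_id", "visit_date"], kind="stable",
                   ignore_index=True)

    age_year = 5 + rng.choice(len(config.age_year_probs), size=n,
                              p=np.asarray(config.age_year_probs))
    age = age_year + rng.random(n)
    dob = index_dates - np.round(age * 365.25).astype("timedelta64[D]")
    sex = np.where(rng.random(n) < np.asarray(config.sex_male_prob)[labels],
                   "M", "F")
    children = pd.DataFrame({
        "child_id": np.arange(n),
        "dob": dob,
        "sex": sex,
        "pdd_flag": np.zeros(n, dtype=int),
    })

    rho = config.covariate_correlation
    p = len(SCALES)
    corr = np.full((p, p), rho) + (1 - rho) * np.eye(p)
    z = rng.standard_normal((n, p)) @ np.linalg.cholesky(corr).T
    scores = (np.asarray(config.covariate_means)[labels]
              + z * np.asarray(config.covariate_sds)[labels])
    scores = np.clip(scores, 0.0, 130.0)
    covariates = pd.DataFrame({"child_id": np.arange(n),
                               "age_at_index": age, "sex": sex})
    for j, col in enumerate(SCALES):
        covariates[col] = scores[:, j]

    return SimulatedCohort(
        visits=visits, children=children, covariates=covariates,
        true_labels=pd.Series(labels, index=np.arange(n), name="true_class"))


def inject_missingness(covariates: pd.DataFrame, config: GeneratorConfig,
                       seed: int | None = None) -> pd.DataFrame:
    """Blank covariate cells at the configured per-scale rates.

    Under MCAR every scale is masked independently at its rate. Under
    MAR-on-Externalizing the Externalizing scale stays MCAR at its own rate,
    while the other three scales' missingness probabilities follow a
    logistic curve in the child's standardized Externalizing score, centred
    so the marginal rate stays near the configured one — children with
    higher Externalizing are more often missing the other scales, which a
    missing-completely-at-random test detects at scale. Demographics are
    never masked.
    """
    rates = np.asarray(config.missing_rates, float)
    if (rates < 0).any() or (rates > 1).any():
        raise ValueError("missing_rates must lie in [0, 1]")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    out = covariates.copy()
    n = len(out)
    if config.missing_mechanism == "MCAR":
        for j, col in enumerate(SCALES):
            out.loc[rng.random(n) < rates[j], col] = np.nan
        return out
    ext = out["ext_t"].to_numpy(float)
    z = (ext - ext.mean()) / ext.std()
    out.loc[rng.random(n) < rates[0], "ext_t"] = np.nan
    for j, col in enumerate(SCALES[1:], start=1):
        if rates[j] <= 0:
            continue
        base = np.log(rates[j] / (1 - rates[j]))
        pmiss = 1.0 / (1.0 + np.exp(-(base + config.mar_slope * z)))
        # recentre so the marginal rate matches the configured one
        pmiss *= rates[j] / pmiss.mean()
        out.loc[rng.random(n) < np.clip(pmiss, 0, 1), col] = np.nan
    return out
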
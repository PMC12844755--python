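"""Virtual study cohorts emulating the teicoplanin development design.

The study data are not deposited, so every pipeline stage is exercised on
synthetic cohorts that reproduce the development cohort's structure: ~100
adults, 40% female, age median 62 (range 18-85), Devine ideal body weight
median ~61.4 kg (range 46.25-77), eGFR median 92.15 mL/min (range 26-141),
albumin median 3.3 g/dL with mild negative correlation to age.  Dosing
follows the clinical protocol: 600 mg infused over 30 min every 12 h for
three loading doses, then once-daily maintenance individualized by TDM;
trough samples are drawn at 24 h and then every 72-96 h, always immediately
pre-dose.  Observations get additive residual noise (default SD 2.61 mg/L)
and values below the 3.0 mg/L LLOQ are excluded from the analysis dataset.

The generator returns the noise-free truth (etas, parameters, clean
concentrations) alongside the noisy dataset so that estimator-recovery
tests can compare against known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .dataset import Observation, StudyDataset, Subject, read_dataset, write_dataset
from .estimation import PopulationModel
from .pk_core import (
    CovariateVector,
    DoseEvent,
    EtaVector,
    PKParameterSet,
    ThetaSet,
    concentration,
    devine_ibw,
    individual_parameters,
)

__all__ = [
    "CohortSpec",
    "SyntheticTruth",
    "SubjectTruth",
    "generate_cohort",
    "generate_design",
    "simulate_observations",
    "generate_dataset",
    "read_dataset",
    "write_dataset",
    "write_truth",
]


@dataclass(frozen=True)
class CohortSpec:
    """Cohort structure and study-design settings.

    Distribution defaults reproduce the development-cohort summary; design
    defaults reproduce the TDM protocol.  ``followup_days`` is a
    (min, max) range of per-subject treatment durations, whose default is
    tuned so the cohort yields ~1.7 samples/subject (168 concentrations in
    100 patients); pass equal min and max for a fixed duration.
    """

    n_subjects: int = 100
    female_fraction: float = 0.40
    age_median: float = 62.0
    age_sd: float = 15.0
    age_range: tuple = (18.0, 85.0)
    height_male: tuple = (172.0, 7.0)      # mean, SD (cm)
    height_female: tuple = (160.0, 6.0)
    ibw_range: tuple = (46.25, 77.0)
    weight_ratio_sigma: float = 0.18       # log-SD of TBW/IBW
    weight_ratio_median: float = 68.0 / 61.4
    weight_range: tuple = (41.0, 127.0)
    egfr_median: float = 92.15
    egfr_sigma_log: float = 0.35
    egfr_range: tuple = (26.0, 141.0)
    alb_median: float = 3.3
    alb_sd: float = 0.45
    alb_range: tuple = (2.4, 4.3)
    alb_age_corr: float = -0.30
    # design
    initial_dose: float = 600.0
    loading_count: int = 3
    loading_interval: float = 12.0
    maintenance_interval: float = 24.0
    infusion_duration: float = 0.5
    first_sample_h: float = 24.0
    sample_gap_range: tuple = (72.0, 96.0)
    followup_days: tuple = (2.0, 9.0)
    tdm_target: float = 15.0
    tdm_clamp: tuple = (0.5, 2.0)
    tdm_round_mg: float = 100.0
    lloq: float = 3.0
    sigma_add: float = 2.61

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("age_range", "ibw_range", "egfr_range", "alb_range",
                     "sample_gap_range", "followup_days", "weight_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: lower bound exceeds upper bound")


@dataclass
class SubjectTruth:
    """Ground truth for one synthetic subject."""

    id: int
    eta: EtaVector
    params: PKParameterSet
    clean_conc: np.ndarray       # noise-free concentrations at sample times
    sample_times: np.ndarray
    n_blq_excluded: int = 0


@dataclass
class SyntheticTruth:
    """Per-subject ground truth retained alongside the noisy dataset."""

    subjects: list

    @property
    def n_blq_excluded(self) -> int:
        return sum(s.n_blq_excluded for s in self.subjects)


def _truncnorm_rvs(rng, mean, sd, lo, hi, size=None):
    if sd <= 0:
        return np.full(size if size is not None else (), float(np.clip(mean, lo, hi)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    if not a < b:
        raise ValueError("infeasible truncation interval")
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _truncnorm_loc(target_median, sd, lo, hi):
    """Location of a truncated normal whose truncated median hits the target."""
    if sd <= 0:
        return target_median

    def trunc_median(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return loc + sd * stats.truncnorm.ppf(0.5, a, b)

    return optimize.brentq(lambda m: trunc_median(m) - target_median,
                           target_median - 2 * sd, target_median + 2 * sd)


def _trunc_lognorm_mu(target_median, sigma_log, lo, hi):
    """Location of a truncated log-normal whose truncated median hits the target.

    Truncation at the upper range bound pulls the median below exp(mu), so
    the location is solved numerically rather than set to log(median).
    """
    llo, lhi = math.log(lo), math.log(hi)

    def trunc_median(mu):
        a, b = (llo - mu) / sigma_log, (lhi - mu) / sigma_log
        return math.exp(mu + sigma_log * stats.truncnorm.ppf(0.5, a, b))

    lt = math.log(target_median)
    return optimize.brentq(lambda mu: trunc_median(mu) - target_median,
                           lt - 2 * sigma_log, lt + 2 * sigma_log)


def generate_cohort(spec: CohortSpec, seed) -> list:
    """Draw covariate vectors for ``spec.n_subjects`` virtual patients.

    Sex is Bernoulli(female_fraction); heights come from sex-specific
    normals truncated so the Devine IBW stays within the cohort range; age
    and albumin are truncated normals; eGFR is a truncated log-normal whose
    truncated median matches the cohort median (sampled directly — the
    creatinine/CKD-EPI step is out of scope).  Albumin is negatively
    correlated with age to mimic the cohort's collinearity.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_subjects
    female = rng.random(n) < spec.female_fraction
    # location shifted so the *truncated* median equals the target median
    age_loc = _truncnorm_loc(spec.age_median, spec.age_sd, *spec.age_range)
    ages = _truncnorm_rvs(rng, age_loc, spec.age_sd, *spec.age_range, size=n)

    heights = np.empty(n)
    for i in range(n):
        sex = "female" if female[i] else "male"
        mean, sd = spec.height_female if female[i] else spec.height_male
        base = 45.5 if female[i] else 50.0
        # height bounds implied by the IBW truncation
        lo = 152.4 + (spec.ibw_range[0] - base) * 2.54 / 2.3
        hi = 152.4 + (spec.ibw_range[1] - base) * 2.54 / 2.3
        heights[i] = _truncnorm_rvs(rng, mean, sd, lo, hi)

    if spec.egfr_sigma_log > 0:
        mu = _trunc_lognorm_mu(spec.egfr_median, spec.egfr_sigma_log, *spec.egfr_range)
        llo, lhi = math.log(spec.egfr_range[0]), math.log(spec.egfr_range[1])
        a, b = (llo - mu) / spec.egfr_sigma_log, (lhi - mu) / spec.egfr_sigma_log
        egfr = np.exp(stats.truncnorm.rvs(a, b, loc=mu, scale=spec.egfr_sigma_log,
                                          size=n, random_state=rng))
    else:
        egfr = np.full(n, spec.egfr_median)

    # albumin: correlated with standardized age, then truncated
    z_age = (ages - spec.age_median) / spec.age_sd if spec.age_sd > 0 else np.zeros(n)
    rho = spec.alb_age_corr
    noise = rng.standard_normal(n)
    alb_raw = spec.alb_median + spec.alb_sd * (
        rho * z_age + math.sqrt(max(0.0, 1 - rho**2)) * noise
    )
    alb = np.clip(alb_raw, *spec.alb_range)

    if spec.weight_ratio_sigma > 0:
        wr = np.exp(math.log(spec.weight_ratio_median)
                    + spec.weight_ratio_sigma * rng.standard_normal(n))
    else:
        wr = np.full(n, spec.weight_ratio_median)

    cohort = []
    for i in range(n):
        sex = "female" if female[i] else "male"
        ibw = devine_ibw(heights[i], sex)
        wt = float(np.clip(ibw * wr[i], *spec.weight_range))
        cohort.append(
            CovariateVector(AGE=float(ages[i]), SEX=sex, HT=float(heights[i]),
                            WT=wt, IBW=ibw, EGFR=float(egfr[i]), ALB=float(alb[i]))
        )
    return cohort


def generate_design(
    cov: CovariateVector,
    spec: CohortSpec,
    rng: np.random.Generator,
    params: PKParameterSet,
) -> tuple[list, np.ndarray, np.ndarray]:
    """Dose events, pre-dose sampling times and measured troughs for one subject.

    Initial regimen: ``initial_dose`` every ``loading_interval`` for
    ``loading_count`` doses, then once-``maintenance_interval`` maintenance
    starting one maintenance interval after the last loading dose.  The
    first sample is drawn at 24 h; later samples follow at uniform-random
    72-96 h gaps snapped to the dosing grid, within a per-subject random
    follow-up window.  TDM emulation: at each sample a measured trough
    (true concentration plus assay noise, as the clinician would see) is
    compared to the 15 mg/L target and all subsequent maintenance doses
    are scaled by clamp(target/measured, 0.5, 2), rounded to 100 mg — a
    simplified, logged stand-in for clinical dose individualization.
    Adjusting on *measured* values keeps the dose assignment a function of
    recorded data only, so maximum-likelihood fits of the resulting
    datasets are not confounded by the design.

    Samples coincide with dose times but are ordered before the dose
    (strictly pre-dose troughs).  Returns ``(doses, sample_times,
    measured_dv)``; the measured values are reused as the dataset's
    observations so the TDM decisions and the analysis data agree.
    """
    followup_h = 24.0 * rng.uniform(*spec.followup_days)
    # planned dose times over the follow-up
    dose_times = [k * spec.loading_interval for k in range(spec.loading_count)]
    t = dose_times[-1] + spec.maintenance_interval
    while t < followup_h:
        dose_times.append(t)
        t += spec.maintenance_interval
    n_loading = spec.loading_count

    # sampling times: first at 24 h, then random 72-96 h gaps on the dose grid
    sample_times = []
    t_s = spec.first_sample_h
    while t_s <= followup_h + 1e-9:
        # snap to the nearest planned dose time (pre-dose sampling)
        nearest = min(dose_times, key=lambda td: abs(td - t_s))
        if not sample_times or nearest > sample_times[-1]:
            sample_times.append(nearest)
        gap = rng.uniform(*spec.sample_gap_range)
        t_s = (sample_times[-1] if sample_times else t_s) + gap

    # build doses with TDM adjustment on the measured trough at each sample
    amounts = np.full(len(dose_times), spec.initial_dose)
    measured = []
    for ts in sample_times:
        events = [
            DoseEvent(td, amounts[j], spec.infusion_duration)
            for j, td in enumerate(dose_times)
            if td < ts
        ]
        true_c = float(concentration(params, events, ts)) if events else 0.0
        dv = true_c + spec.sigma_add * rng.standard_normal()
        while dv < 0:
            dv = true_c + spec.sigma_add * rng.standard_normal()
        measured.append(dv)
        basis = max(dv, spec.lloq / 2)  # a BLQ report still drives a dose increase
        factor = float(np.clip(spec.tdm_target / basis, *spec.tdm_clamp))
        new_amt = max(
            spec.tdm_round_mg,
            round(spec.initial_dose * factor / spec.tdm_round_mg) * spec.tdm_round_mg,
        )
        for j, td in enumerate(dose_times):
            if td >= ts and j >= n_loading:
                amounts[j] = new_amt

    doses = [DoseEvent(td, float(a), spec.infusion_duration)
             for td, a in zip(dose_times, amounts)]
    return (doses, np.asarray(sample_times, dtype=float),
            np.asarray(measured, dtype=float))


def simulate_observations(
    params: PKParameterSet,
    doses: list,
    sample_times: np.ndarray,
    spec: CohortSpec,
    rng: np.random.Generator,
    measured_dv: np.ndarray | None = None,
) -> tuple[list, np.ndarray, int]:
    """Noisy observations at the sampling times with BLQ exclusion.

    DV = true concentration + N(0, sigma_add^2); negative draws are
    redrawn.  When :func:`generate_design` already produced the measured
    values (its TDM decisions are based on them), pass them as
    ``measured_dv`` so the analysis data match the values that drove the
    dose adjustments.  Values below the LLOQ are excluded from the
    analysis observations and counted.  Returns (kept observations,
    noise-free concentrations, number excluded).
    """
    clean = np.asarray(concentration(params, doses, sample_times), dtype=float)
    clean = np.atleast_1d(clean)
    obs, n_blq = [], 0
    for j, (t, c) in enumerate(zip(sample_times, clean)):
        if measured_dv is not None:
            dv = float(measured_dv[j])
        else:
            dv = c + spec.sigma_add * rng.standard_normal()
            while dv < 0:
                dv = c + spec.sigma_add * rng.standard_normal()
        if dv < spec.lloq:
            n_blq += 1
            continue
        obs.append(Observation(float(t), float(dv)))
    return obs, clean, n_blq


def generate_dataset(
    spec: CohortSpec | None = None,
    seed=0,
    model: PopulationModel | None = None,
) -> tuple[StudyDataset, SyntheticTruth]:
    """One full synthetic study: cohort, design, truth and noisy dataset.

    Concentrations are simulated from ``model`` (default: the published
    final model) with etas drawn from its Omega.  Subjects whose every
    observation falls below the LLOQ are retained in the dataset with no
    observations (they drop out of fitting with a warning).
    """
    spec = spec or CohortSpec()
    model = model or PopulationModel.published()
    ts = _thetaset_from_model(model)
    rng = np.random.default_rng(seed)
    cohort = generate_cohort(spec, rng.integers(2**31))
    w = model.omega.diag
    subjects, truths = [], []
    for i, cov in enumerate(cohort):
        eta = EtaVector(
            eta_cl=float(math.sqrt(w[0]) * rng.standard_normal()),
            eta_v=float(math.sqrt(w[1]) * rng.standard_normal()),
        )
        params = individual_parameters(ts, cov, eta)
        doses, sample_times, measured = generate_design(cov, spec, rng, params)
        obs, clean, n_blq = simulate_observations(
            params, doses, sample_times, spec, rng, measured_dv=measured
        )
        subjects.append(Subject(i + 1, doses, obs, cov))
        truths.append(SubjectTruth(i + 1, eta, params, clean, sample_times, n_blq))
    return StudyDataset(subjects), SyntheticTruth(truths)


def write_truth(truth: SyntheticTruth, path) -> None:
    """Write the ground-truth sidecar as CSV (one row per sampling time).

    Columns: ID, ETA_CL, ETA_V, CL, V, TIME, CLEAN_CONC.  Kept separate
    from the analysis dataset so estimator-recovery experiments can load
    the generating values without touching the NONMEM-style table.
    """
    import pandas as pd

    rows = []
    for s in truth.subjects:
        for t, c in zip(s.sample_times, s.clean_conc):
            rows.append({
                "ID": s.id,
                "ETA_CL": s.eta.eta_cl,
                "ETA_V": s.eta.eta_v,
                "CL": s.params.CL,
                "V": s.params.V,
                "TIME": t,
                "CLEAN_CONC": c,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def _thetaset_from_model(model: PopulationModel) -> ThetaSet:
    by_name = {e.name: e for e in model.spec.effects}
    unknown = set(by_name) - {"EGFR_CL", "IBW_CL", "AGE_CL"}
    if unknown:
        raise ValueError(
            f"model has covariate effects outside the canonical clearance model: {sorted(unknown)}"
        )
    return ThetaSet(
        CLpop=model.theta["CLpop"],
        Vpop=model.theta["Vpop"],
        th_egfr=model.theta.get("EGFR_CL", 0.0),
        th_ibw=model.theta.get("IBW_CL", 0.0),
        th_age=model.theta.get("AGE_CL", 0.0),
        egfr_ref=by_name["EGFR_CL"].ref if "EGFR_CL" in by_name else 92.15,
        ibw_ref=by_name["IBW_CL"].ref if "IBW_CL" in by_name else 61.0,
        age_ref=by_name["AGE_CL"].ref if "AGE_CL" in by_name else 62.0,
    )
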
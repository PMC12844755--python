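"""Model qualification: goodness of fit, bootstrap, pcVPC, external validation.

CWRES uses the FOCE linearization: the observation vector is expanded to
first order about the conditional mode eta_hat,

    y ~ N( f(eta_hat) - G eta_hat,  G Omega G' + sigma^2 I ),

and the residual is whitened by the Cholesky factor of that covariance, so
it is approximately standard normal under a correctly specified model.

The nonparametric bootstrap resamples subjects with replacement to the
original cohort size and refits; replicates that fail to converge or end
at a parameter-space boundary are discarded and counted.

The prediction-corrected VPC normalizes each observed and simulated value
by (bin median population prediction / its own population prediction)
before computing percentiles, removing trivial variability from dose and
covariate differences within a bin.

External validation bias/precision: MPE = mean((Cpred - Cobs)/Cobs) * 100,
MAPE = mean(|Cpred - Cobs|/Cobs) * 100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, solve_triangular

from .dataset import StudyDataset, Subject
from .estimation import (
    FitResult,
    ModelSpec,
    PopulationModel,
    _eta_jacobian,
    _eta_mode,
    _SubjData,
    fit_model,
)

__all__ = [
    "cwres",
    "bootstrap",
    "BootstrapSummary",
    "pcvpc",
    "VpcSummary",
    "external_validate",
    "validate_dataset",
]

logger = logging.getLogger(__name__)


def cwres(fit_or_model, dataset: StudyDataset) -> pd.DataFrame:
    """Goodness-of-fit table with conditional weighted residuals.

    One row per retained observation: subject id, time, observed value,
    population prediction (eta = 0), individual prediction (at the EBE)
    and CWRES.  Rows whose linearized covariance is numerically singular
    are flagged in the ``singular`` column with CWRES set to NaN.
    """
    pm = fit_or_model.model if isinstance(fit_or_model, FitResult) else fit_or_model
    omega2 = pm.omega.diag
    sigma = pm.sigma.sd
    rows = []
    for subj in dataset:
        if not subj.observations:
            continue
        sd = _SubjData(subj, pm.spec)
        tvcl, tvv = sd.typical(pm.theta)
        eta = _eta_mode(sd, tvcl, tvv, omega2, sigma)
        pred_pop = sd.predict(tvcl, tvv, np.zeros(2))
        pred_ind = sd.predict(tvcl, tvv, eta)
        free = omega2 > 0
        singular = False
        if free.any():
            G = _eta_jacobian(sd, tvcl, tvv, eta, free)
            cov = G @ np.diag(omega2[free]) @ G.T + sigma**2 * np.eye(sd.n)
            mean = pred_ind - G @ eta[free]
            try:
                L = cholesky(cov, lower=True)
                w = solve_triangular(L, sd.y - mean, lower=True)
            except np.linalg.LinAlgError:
                singular = True
                w = np.full(sd.n, np.nan)
        else:
            w = (sd.y - pred_pop) / sigma
        for j in range(sd.n):
            rows.append({
                "id": subj.id,
                "time": sd.t[j],
                "observed": sd.y[j],
                "population_prediction": pred_pop[j],
                "individual_prediction": pred_ind[j],
                "cwres": w[j],
                "singular": singular,
            })
    return pd.DataFrame(rows)


@dataclass
class BootstrapSummary:
    """Bootstrap medians and percentile 95% CIs per reported parameter."""

    table: pd.DataFrame        # index: parameter; columns: median, ci95_low, ci95_high
    estimates: pd.DataFrame    # one row per successful replicate
    n_success: int
    n_discarded: int

    @property
    def replicates(self) -> int:
        return self.n_success + self.n_discarded

    def ci(self, parameter: str) -> tuple:
        row = self.table.loc[parameter]
        return float(row["ci95_low"]), float(row["ci95_high"])


def _fit_to_row(fit: FitResult) -> dict:
    row = dict(fit.theta)
    row["IIV_CL_cv_pct"] = fit.omega.cv_pct("CL")
    row["IIV_V_cv_pct"] = fit.omega.cv_pct("V")
    row["sigma"] = fit.sigma.sd
    return row


def bootstrap(
    dataset: StudyDataset,
    spec: ModelSpec,
    replicates: int = 1000,
    seed=0,
    *,
    resample: bool = True,
    maxiter: int = 300,
    inits: dict | None = None,
) -> BootstrapSummary:
    """Nonparametric bootstrap of the population fit.

    Subjects are resampled with replacement to the original cohort size
    (``resample=False`` refits the original dataset every time, a
    degenerate mode used for testing).  Replicates that do not converge or
    that end on a parameter boundary are discarded; the summary reports
    medians and percentile 2.5/97.5 limits of the retained estimates.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(dataset.subjects)
    rows = []
    n_discarded = 0
    for r in range(replicates):
        if resample:
            idx = rng.integers(0, n, size=n)
            subs = [dataset.subjects[i] for i in idx]
            boot = StudyDataset([
                Subject(f"{s.id}#{k}", s.doses, s.observations, s.covariates)
                for k, s in enumerate(subs)
            ])
        else:
            boot = dataset
        try:
            fit = fit_model(boot, spec, inits=inits, maxiter=maxiter)
        except Exception as exc:
            logger.warning("bootstrap replicate %d failed: %s", r, exc)
            n_discarded += 1
            continue
        if not fit.converged or fit.boundary:
            n_discarded += 1
            continue
        rows.append(_fit_to_row(fit))
    if not rows:
        raise RuntimeError("all bootstrap replicates failed or were discarded")
    est = pd.DataFrame(rows)
    table = pd.DataFrame({
        "median": est.median(),
        "ci95_low": est.quantile(0.025),
        "ci95_high": est.quantile(0.975),
    })
    return BootstrapSummary(table=table, estimates=est,
                            n_success=len(rows), n_discarded=n_discarded)


@dataclass
class VpcSummary:
    """Prediction-corrected VPC summary per time bin."""

    table: pd.DataFrame
    # columns: bin_mid, n_observations, obs_p5/p50/p95,
    #          sim_p{5,50,95}_lo / _hi (95% CI of each simulated percentile)
    n_sim: int
    percentiles: tuple = (5.0, 50.0, 95.0)


def _equal_count_bins(times: np.ndarray, n_bins: int, min_per_bin: int = 5):
    """Quantile bin edges on time; bins under ``min_per_bin`` merge rightward."""
    qs = np.linspace(0, 1, n_bins + 1)
    edges = np.unique(np.quantile(times, qs))
    while len(edges) > 2:
        idx = np.clip(np.searchsorted(edges, times, side="right") - 1, 0, len(edges) - 2)
        counts = np.bincount(idx, minlength=len(edges) - 1)
        if counts.min() >= min_per_bin:
            break
        k = int(np.argmin(counts))
        drop = k + 1 if k + 1 < len(edges) - 1 else k
        logger.info("merging sparse VPC bin at edge %.3g", edges[drop])
        edges = np.delete(edges, drop)
    return edges


def pcvpc(
    dataset: StudyDataset,
    fit_or_model,
    n_sim: int = 1000,
    bins: int = 6,
    seed=0,
    *,
    max_time: float | None = None,
    percentiles: tuple = (5.0, 50.0, 95.0),
) -> VpcSummary:
    """Prediction-corrected visual predictive check.

    ``n_sim`` replicate datasets are simulated from the model on the
    observed design (same subjects, dose histories and sampling times;
    eta ~ N(0, Omega), additive residual noise).  Each observed and
    simulated value is corrected multiplicatively by (bin median population
    prediction / its own population prediction); binning is equal-count on
    observation time (bins with fewer than 5 observations merge with a
    neighbor).  Reported per bin: corrected observed percentiles and the
    2.5-97.5% envelope of each simulated percentile.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    pm = fit_or_model.model if isinstance(fit_or_model, FitResult) else fit_or_model
    rng = np.random.default_rng(seed)
    omega2 = pm.omega.diag
    sigma = pm.sigma.sd

    subs, times, y, pred = [], [], [], []
    for subj in dataset:
        if not subj.observations:
            continue
        sd = _SubjData(subj, pm.spec)
        keep = np.ones(sd.n, dtype=bool) if max_time is None else sd.t <= max_time
        if not keep.any():
            continue
        tvcl, tvv = sd.typical(pm.theta)
        subs.append((sd, tvcl, tvv, keep))
        times.append(sd.t[keep])
        y.append(sd.y[keep])
        pred.append(sd.predict(tvcl, tvv, np.zeros(2))[keep])
    times = np.concatenate(times)
    y = np.concatenate(y)
    pred = np.concatenate(pred)

    edges = _equal_count_bins(times, bins)
    bin_idx = np.clip(np.searchsorted(edges, times, side="right") - 1, 0, len(edges) - 2)
    bin_med_pred = np.array([
        np.median(pred[bin_idx == b]) for b in range(len(edges) - 1)
    ])
    pc_obs = y * bin_med_pred[bin_idx] / pred

    # simulate replicates on the same design
    w = np.sqrt(omega2)
    sim_pc = np.empty((n_sim, len(times)))
    for r in range(n_sim):
        vals = []
        for sd, tvcl, tvv, keep in subs:
            eta = w * rng.standard_normal(2)
            f = sd.predict(tvcl, tvv, eta)[keep]
            vals.append(f + sigma * rng.standard_normal(keep.sum()))
        sim = np.concatenate(vals)
        sim_pc[r] = sim * bin_med_pred[bin_idx] / pred

    rows = []
    for b in range(len(edges) - 1):
        m = bin_idx == b
        row = {
            "bin_lo": edges[b],
            "bin_hi": edges[b + 1],
            "bin_mid": float(np.median(times[m])),
            "n_observations": int(m.sum()),
        }
        for p in percentiles:
            row[f"obs_p{p:g}"] = float(np.percentile(pc_obs[m], p))
            sim_p = np.percentile(sim_pc[:, m], p, axis=1)
            row[f"sim_p{p:g}_lo"] = float(np.percentile(sim_p, 2.5))
            row[f"sim_p{p:g}_med"] = float(np.percentile(sim_p, 50.0))
            row[f"sim_p{p:g}_hi"] = float(np.percentile(sim_p, 97.5))
        rows.append(row)
    return VpcSummary(table=pd.DataFrame(rows), n_sim=n_sim, percentiles=percentiles)


def external_validate(predictions, observations) -> tuple:
    """Mean prediction error and mean absolute prediction error, in percent.

    MPE (bias) is the mean signed relative error of predictions against
    observations; MAPE (precision) the mean absolute relative error.
    Always MAPE >= |MPE|; both are invariant to rescaling both inputs.
    """
    pred = np.asarray(predictions, dtype=float)
    obs = np.asarray(observations, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("predictions and observations must be paired")
    if np.any(obs == 0):
        raise ValueError("zero observation: relative error undefined")
    rel = (pred - obs) / obs
    return float(rel.mean() * 100.0), float(np.abs(rel).mean() * 100.0)


def validate_dataset(
    dataset: StudyDataset, model: PopulationModel, *, use_map: bool = False
) -> dict:
    """External-validation metrics of a model on an independent dataset.

    Population (eta = 0) predictions by default — a priori predictive
    performance; ``use_map=True`` conditions each subject's prediction on
    its own observations (MAP) instead.
    """
    preds, obs = [], []
    for subj in dataset:
        if not subj.observations:
            continue
        sd = _SubjData(subj, model.spec)
        tvcl, tvv = sd.typical(model.theta)
        if use_map:
            eta = _eta_mode(sd, tvcl, tvv, model.omega.diag, model.sigma.sd)
        else:
            eta = np.zeros(2)
        preds.append(sd.predict(tvcl, tvv, eta))
        obs.append(sd.y)
    mpe, mape = external_validate(np.concatenate(preds), np.concatenate(obs))
    return {"MPE_pct": mpe, "MAPE_pct": mape, "n": int(sum(len(p) for p in preds))}
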
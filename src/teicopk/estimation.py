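"""Nonlinear mixed-effects estimation for the teicoplanin model.

The marginal likelihood of each subject's concentrations is approximated by
a Laplace expansion about the conditional mode of the random effects
(empirical Bayes estimate).  With a purely additive residual error the
residual variance does not depend on eta, so this approximation coincides
with the first-order conditional estimation method with interaction
(FOCE-I) used by NONMEM-style software; objective function values (OFV,
-2 log-likelihood including all constants) are therefore directly
comparable across nested models.

Per subject i with observations y, model predictions f(eta), diagonal
random-effect variances Omega = diag(omega2) and additive error SD sigma:

    eta_hat = argmin  ||y - f(eta)||^2 / sigma^2  +  eta' Omega^-1 eta
    OFV_i   = ||y - f(eta_hat)||^2/sigma^2 + n log(2 pi sigma^2)
              + eta_hat' Omega^-1 eta_hat + log det(I + (G'G/sigma^2) Omega)

with G = df/deta at the mode (Gauss-Newton curvature).  The last term is
written so the Omega -> 0 limit (etas pinned at zero) is exact.

Positivity of CLpop, Vpop, sigma and the omega2 is enforced by estimating
them on the log scale; covariate coefficients (power exponents, linear
slopes) are estimated on the identity scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .dataset import StudyDataset, Subject
from .pk_core import CovariateVector, EtaVector, ThetaSet, _conc_arrays

__all__ = [
    "CovariateEffect",
    "ModelSpec",
    "OmegaMatrix",
    "SigmaSpec",
    "PopulationModel",
    "FitResult",
    "final_model_spec",
    "base_model_spec",
    "conditional_eta",
    "predict_subject",
    "foce_objective",
    "fit_model",
    "eta_shrinkage",
    "standard_errors",
]

logger = logging.getLogger(__name__)

_BOUND = 12.0          # optimizer box on log-scale parameters
_BOUND_POWER = 25.0    # optimizer box on power exponents
_BOUNDARY_TOL = 1e-3   # "at the boundary" if within this of the box


class DomainError(ValueError):
    """Covariate model evaluated outside its valid domain (e.g. age term <= 0)."""


@dataclass(frozen=True)
class CovariateEffect:
    """One covariate-parameter relationship in the structural model.

    forms:
      power        factor = (x / ref) ** theta
      linear       factor = 1 + theta * (x - ref)
      categorical  factor = 1 + theta * indicator(x)
    """

    covariate: str
    parameter: str              # "CL" or "V"
    form: str                   # "power" | "linear" | "categorical"
    ref: float = 0.0
    init: float = 0.0

    def __post_init__(self) -> None:
        if self.parameter not in ("CL", "V"):
            raise ValueError(f"parameter must be CL or V, got {self.parameter!r}")
        if self.form not in ("power", "linear", "categorical"):
            raise ValueError(f"unknown form {self.form!r}")

    @property
    def name(self) -> str:
        return f"{self.covariate}_{self.parameter}"


@dataclass(frozen=True)
class ModelSpec:
    """Structural/stochastic model description for fitting.

    ``fix`` names parameters held at their initial values (excluded from
    estimation and from the RSE table).  The error model is additive; this
    is the structure selected for teicoplanin trough data, where
    proportional components are poorly identifiable.
    """

    effects: tuple[CovariateEffect, ...] = ()
    cl_init: float = 1.0
    v_init: float = 80.0
    omega2_cl_init: float = 0.09
    omega2_v_init: float = 0.09
    sigma_init: float = 3.0
    error: str = "additive"
    fix: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.error != "additive":
            raise ValueError("only the additive error model is supported")
        names = [e.name for e in self.effects]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate covariate effects: {names}")

    @property
    def param_names(self) -> tuple[str, ...]:
        return (
            "CLpop",
            "Vpop",
            *[e.name for e in self.effects],
            "omega2_CL",
            "omega2_V",
            "sigma",
        )

    def initial_values(self) -> dict[str, float]:
        vals = {
            "CLpop": self.cl_init,
            "Vpop": self.v_init,
            "omega2_CL": self.omega2_cl_init,
            "omega2_V": self.omega2_v_init,
            "sigma": self.sigma_init,
        }
        for e in self.effects:
            vals[e.name] = e.init
        return vals


def final_model_spec(
    egfr_ref: float = 92.15, ibw_ref: float = 61.0, age_ref: float = 62.0
) -> ModelSpec:
    """The final three-covariate clearance model (eGFR, IBW powers; centered age).

    Reference values default to the development-cohort medians; pass
    dataset medians to renormalize.  Initial coefficient values are the
    literature-scale defaults, not the published estimates.
    """
    return ModelSpec(
        effects=(
            CovariateEffect("EGFR", "CL", "power", ref=egfr_ref, init=0.75),
            CovariateEffect("IBW", "CL", "power", ref=ibw_ref, init=1.0),
            CovariateEffect("AGE", "CL", "linear", ref=age_ref, init=0.0),
        )
    )


def base_model_spec() -> ModelSpec:
    """Covariate-free one-compartment model (SCM starting point)."""
    return ModelSpec()


@dataclass(frozen=True)
class OmegaMatrix:
    """Diagonal between-subject variance matrix (log-scale variances)."""

    omega2_cl: float
    omega2_v: float

    def __post_init__(self) -> None:
        if self.omega2_cl < 0 or self.omega2_v < 0:
            raise ValueError("omega^2 must be nonnegative")

    @property
    def diag(self) -> np.ndarray:
        return np.array([self.omega2_cl, self.omega2_v])

    def cv_pct(self, which: str) -> float:
        """IIV as CV% using the 100*omega convention (common in PopPK reports)."""
        w2 = self.omega2_cl if which == "CL" else self.omega2_v
        return 100.0 * math.sqrt(w2)

    def cv_pct_lognormal(self, which: str) -> float:
        """Exact log-normal CV%: 100*sqrt(exp(omega^2) - 1)."""
        w2 = self.omega2_cl if which == "CL" else self.omega2_v
        return 100.0 * math.sqrt(math.expm1(w2))


@dataclass(frozen=True)
class SigmaSpec:
    """Additive residual error standard deviation (mg/L)."""

    sd: float
    model: str = "additive"

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError(f"sigma must be positive, got {self.sd}")


@dataclass(frozen=True)
class PopulationModel:
    """A complete population model: structure, fixed effects, Omega, sigma."""

    spec: ModelSpec
    theta: dict
    omega: OmegaMatrix
    sigma: SigmaSpec

    @classmethod
    def published(cls) -> "PopulationModel":
        """The published final model: Table-2 point estimates."""
        spec = final_model_spec()
        ts = ThetaSet.final()
        theta = {
            "CLpop": ts.CLpop,
            "Vpop": ts.Vpop,
            "EGFR_CL": ts.th_egfr,
            "IBW_CL": ts.th_ibw,
            "AGE_CL": ts.th_age,
        }
        return cls(
            spec=spec,
            theta=theta,
            omega=OmegaMatrix(0.341**2, 0.310**2),
            sigma=SigmaSpec(2.61),
        )

    @classmethod
    def from_thetaset(
        cls, ts: ThetaSet, omega: OmegaMatrix, sigma: SigmaSpec
    ) -> "PopulationModel":
        spec = final_model_spec(ts.egfr_ref, ts.ibw_ref, ts.age_ref)
        theta = {
            "CLpop": ts.CLpop,
            "Vpop": ts.Vpop,
            "EGFR_CL": ts.th_egfr,
            "IBW_CL": ts.th_ibw,
            "AGE_CL": ts.th_age,
        }
        return cls(spec=spec, theta=theta, omega=omega, sigma=sigma)


# ---------------------------------------------------------------------------
# internal per-subject machinery


def _covariate_value(cov: CovariateVector, name: str) -> float:
    if name == "SEX":
        return 1.0 if cov.SEX == "female" else 0.0
    v = getattr(cov, name)
    if v is None:
        raise ValueError(f"covariate {name} missing for screening/effect evaluation")
    return float(v)


class _SubjData:
    """Preprocessed per-subject arrays for fast repeated evaluation."""

    __slots__ = ("sid", "dose_t", "dose_amt", "dose_dur", "t", "y", "n", "eff_x", "spec")

    def __init__(self, subject: Subject, spec: ModelSpec):
        self.sid = subject.id
        self.spec = spec
        self.dose_t = np.array([d.time for d in subject.doses])
        self.dose_amt = np.array([d.amount for d in subject.doses])
        self.dose_dur = np.array([d.duration for d in subject.doses])
        self.t = subject.obs_times
        self.y = subject.dv
        self.n = len(self.t)
        # covariate value at each observation time (carry-forward rule)
        self.eff_x = [
            np.array([_covariate_value(subject.covariates_at(tt), e.covariate) for tt in self.t])
            for e in spec.effects
        ]

    def typical(self, theta: dict) -> tuple[np.ndarray, np.ndarray]:
        """Typical CL and V per observation (may vary with time-varying covariates)."""
        tvcl = np.full(self.n, theta["CLpop"])
        tvv = np.full(self.n, theta["Vpop"])
        for e, x in zip(self.spec.effects, self.eff_x):
            c = theta[e.name]
            if e.form == "power":
                fac = (x / e.ref) ** c
            else:  # linear / categorical share the 1 + c*(...) shape
                fac = 1.0 + c * ((x - e.ref) if e.form == "linear" else x)
                if np.any(fac <= 0):
                    raise DomainError(
                        f"{e.name}: factor <= 0 for subject {self.sid} "
                        f"(coefficient {c:.4g})"
                    )
            if e.parameter == "CL":
                tvcl = tvcl * fac
            else:
                tvv = tvv * fac
        return tvcl, tvv

    def predict(self, tvcl: np.ndarray, tvv: np.ndarray, eta: np.ndarray) -> np.ndarray:
        cl = tvcl * math.exp(eta[0])
        v = tvv * math.exp(eta[1])
        return _conc_arrays(cl, v, self.dose_t, self.dose_amt, self.dose_dur, self.t)


def _lm_minimize(resid, jac, z0, max_iter=60, gtol=1e-8, xtol=1e-10):
    """Small dense Levenberg-Marquardt (the inner problem is 1-2 dimensional).

    Returns the minimizer of ||resid(z)||^2.  Hand-rolled to avoid solver
    overhead in the innermost loop of the population fit.
    """
    z = np.asarray(z0, dtype=float).copy()
    r = resid(z)
    if not np.all(np.isfinite(r)):
        raise ValueError("non-finite residuals at inner starting point")
    cost = float(r @ r)
    lam = 1e-3
    k = len(z)
    eye = np.eye(k)
    for _ in range(max_iter):
        J = jac(z)
        g = J.T @ r
        if np.max(np.abs(g)) <= gtol * max(1.0, cost):
            break
        A = J.T @ J
        improved = False
        for _ in range(25):
            try:
                step = np.linalg.solve(A + lam * (np.diag(np.diag(A)) + 1e-12 * eye), -g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            z_new = z + step
            r_new = resid(z_new)
            cost_new = float(r_new @ r_new) if np.all(np.isfinite(r_new)) else np.inf
            if cost_new < cost:
                z, r, cost = z_new, r_new, cost_new
                lam = max(lam * 0.3, 1e-12)
                improved = True
                break
            lam *= 10.0
        if not improved or np.max(np.abs(step)) <= xtol * (1.0 + np.max(np.abs(z))):
            break
    return z, cost


def _eta_mode(
    sd: _SubjData,
    tvcl: np.ndarray,
    tvv: np.ndarray,
    omega2: np.ndarray,
    sigma: float,
    x0: np.ndarray | None = None,
) -> np.ndarray:
    """Conditional mode of eta: penalized nonlinear least squares.

    Components with omega2 = 0 are pinned at zero (infinite shrinkage
    limit).  Solved by Levenberg-Marquardt on the stacked residual vector
    [(y - f)/sigma ; eta/omega]; tried from the warm start and from zero,
    keeping the lower joint objective.
    """
    free = omega2 > 0
    eta = np.zeros(2)
    if not free.any() or sd.n == 0:
        return eta
    w = np.sqrt(omega2[free])
    nf = int(free.sum())
    h = 1e-6

    def resid(z: np.ndarray) -> np.ndarray:
        e = np.zeros(2)
        e[free] = z
        f = sd.predict(tvcl, tvv, e)
        return np.concatenate([(sd.y - f) / sigma, z / w])

    def jac(z: np.ndarray) -> np.ndarray:
        e = np.zeros(2)
        e[free] = z
        cols = []
        for k in np.flatnonzero(free):
            ep, em = e.copy(), e.copy()
            ep[k] += h
            em[k] -= h
            cols.append(-(sd.predict(tvcl, tvv, ep) - sd.predict(tvcl, tvv, em)) / (2 * h * sigma))
        J = np.zeros((sd.n + nf, nf))
        J[: sd.n] = np.column_stack(cols)
        J[sd.n:] = np.diag(1.0 / w)
        return J

    starts = [np.zeros(nf)]
    if x0 is not None and np.any(x0[free] != 0):
        starts.insert(0, x0[free])
    best_z, best_obj = None, np.inf
    for z0 in starts:
        z, obj = _lm_minimize(resid, jac, z0)
        if obj < best_obj - 1e-12:
            best_z, best_obj = z, obj
    eta[free] = best_z
    return eta


def _subject_ofv(
    sd: _SubjData,
    tvcl: np.ndarray,
    tvv: np.ndarray,
    omega2: np.ndarray,
    sigma: float,
    eta_hat: np.ndarray,
) -> float:
    """-2 log Laplace-approximate marginal likelihood, all constants included."""
    f = sd.predict(tvcl, tvv, eta_hat)
    r = sd.y - f
    ofv = float(r @ r) / sigma**2 + sd.n * math.log(2 * math.pi * sigma**2)
    free = omega2 > 0
    if not free.any():
        return ofv
    ofv += float((eta_hat[free] ** 2 / omega2[free]).sum())
    G = _eta_jacobian(sd, tvcl, tvv, eta_hat, free)
    gtg = G.T @ G / sigma**2
    m = np.eye(free.sum()) + gtg * omega2[free][None, :]
    sign, logdet = np.linalg.slogdet(m)
    if sign <= 0:  # cannot happen for exact arithmetic; guard round-off
        raise FloatingPointError("non-positive determinant in Laplace term")
    return ofv + float(logdet)


def _eta_jacobian(
    sd: _SubjData,
    tvcl: np.ndarray,
    tvv: np.ndarray,
    eta: np.ndarray,
    free: np.ndarray,
    h: float = 1e-5,
) -> np.ndarray:
    """Central-difference df/deta (n_obs x n_free) at eta."""
    cols = []
    for k in range(2):
        if not free[k]:
            continue
        ep, em = eta.copy(), eta.copy()
        ep[k] += h
        em[k] -= h
        cols.append((sd.predict(tvcl, tvv, ep) - sd.predict(tvcl, tvv, em)) / (2 * h))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# parameter packing / transforms

_LOG_PARAMS = {"CLpop", "Vpop", "omega2_CL", "omega2_V", "sigma"}


def _to_est_scale(name: str, value: float) -> float:
    return math.log(value) if name in _LOG_PARAMS else value


def _from_est_scale(name: str, x: float) -> float:
    return math.exp(x) if name in _LOG_PARAMS else x


def _resolve_model(model, omega=None, sigma=None) -> PopulationModel:
    """Accept a PopulationModel, or a ThetaSet plus explicit omega/sigma."""
    if isinstance(model, PopulationModel):
        return model
    if isinstance(model, ThetaSet):
        if omega is None or sigma is None:
            raise ValueError("omega and sigma required with a ThetaSet")
        if not isinstance(sigma, SigmaSpec):
            sigma = SigmaSpec(float(sigma))
        return PopulationModel.from_thetaset(model, omega, sigma)
    raise TypeError(f"expected PopulationModel or ThetaSet, got {type(model)!r}")


# ---------------------------------------------------------------------------
# public operations


def conditional_eta(subject: Subject, model, omega=None, sigma=None) -> EtaVector:
    """Empirical Bayes estimate (conditional mode) of one subject's etas.

    ``model`` is a :class:`PopulationModel`, or a :class:`ThetaSet` with
    ``omega`` (:class:`OmegaMatrix`) and ``sigma`` given separately.
    Subjects need at least one retained observation.
    """
    pm = _resolve_model(model, omega, sigma)
    if not subject.observations:
        raise ValueError(f"subject {subject.id} has no observations")
    sd = _SubjData(subject, pm.spec)
    tvcl, tvv = sd.typical(pm.theta)
    eta = _eta_mode(sd, tvcl, tvv, pm.omega.diag, pm.sigma.sd)
    return EtaVector(eta_cl=float(eta[0]), eta_v=float(eta[1]))


def predict_subject(subject: Subject, model, eta: EtaVector | None = None) -> np.ndarray:
    """Model-predicted concentrations at the subject's observation times.

    ``eta=None`` gives population predictions (eta = 0); pass the EBE for
    individual predictions.
    """
    pm = _resolve_model(model)
    sd = _SubjData(subject, pm.spec)
    tvcl, tvv = sd.typical(pm.theta)
    e = np.zeros(2) if eta is None else np.array([eta.eta_cl, eta.eta_v])
    return sd.predict(tvcl, tvv, e)


def foce_objective(dataset: StudyDataset, model, omega=None, sigma=None) -> float:
    """FOCE/Laplace objective function value (-2 log marginal likelihood).

    Deterministic given inputs; sums independent per-subject contributions,
    so it is invariant to subject order and additive over duplicated
    subjects.
    """
    pm = _resolve_model(model, omega, sigma)
    total = 0.0
    for subj in dataset:
        if not subj.observations:
            continue
        sd = _SubjData(subj, pm.spec)
        tvcl, tvv = sd.typical(pm.theta)
        eta = _eta_mode(sd, tvcl, tvv, pm.omega.diag, pm.sigma.sd)
        total += _subject_ofv(sd, tvcl, tvv, pm.omega.diag, pm.sigma.sd, eta)
    return total


@dataclass
class FitResult:
    """Result of a population fit.

    ``theta`` holds the structural fixed effects by name (natural scale);
    ``ebes`` the per-subject conditional modes at the optimum, aligned with
    ``subject_ids``.  ``rse_pct`` is populated by :func:`standard_errors`.
    """

    spec: ModelSpec
    theta: dict
    omega: OmegaMatrix
    sigma: SigmaSpec
    ofv: float
    ebes: list
    subject_ids: list
    converged: bool
    boundary: bool
    n_subjects: int = 0
    n_obs: int = 0
    se: dict = field(default_factory=dict)
    rse_pct: dict = field(default_factory=dict)
    message: str = ""

    @property
    def model(self) -> PopulationModel:
        return PopulationModel(self.spec, dict(self.theta), self.omega, self.sigma)

    def shrinkage_pct(self) -> dict:
        return eta_shrinkage(self)

    def to_thetaset(self) -> ThetaSet:
        """Map the canonical three-covariate fit onto a :class:`ThetaSet`."""
        by_name = {e.name: e for e in self.spec.effects}
        needed = {"EGFR_CL", "IBW_CL", "AGE_CL"}
        if set(by_name) != needed:
            raise ValueError("fit does not use the canonical final-model structure")
        return ThetaSet(
            CLpop=self.theta["CLpop"],
            Vpop=self.theta["Vpop"],
            th_egfr=self.theta["EGFR_CL"],
            th_ibw=self.theta["IBW_CL"],
            th_age=self.theta["AGE_CL"],
            egfr_ref=by_name["EGFR_CL"].ref,
            ibw_ref=by_name["IBW_CL"].ref,
            age_ref=by_name["AGE_CL"].ref,
        )

    def summary(self) -> str:
        """Human-readable parameter table (final-model layout)."""
        lines = [f"OFV {self.ofv:.3f}  converged={self.converged}  "
                 f"n={self.n_subjects} subjects / {self.n_obs} observations"]
        shr = eta_shrinkage(self)
        rows = [("CLpop (L/h)", self.theta["CLpop"], "CLpop")]
        for e in self.spec.effects:
            rows.append((f"{e.covariate}-{e.parameter} ({e.form})", self.theta[e.name], e.name))
        rows += [
            ("Vpop (L)", self.theta["Vpop"], "Vpop"),
            ("IIV-CL (CV%)", self.omega.cv_pct("CL"), "omega2_CL"),
            ("IIV-V (CV%)", self.omega.cv_pct("V"), "omega2_V"),
            ("RUV additive (mg/L)", self.sigma.sd, "sigma"),
        ]
        for label, val, pname in rows:
            rse = self.rse_pct.get(pname)
            rse_s = f"  RSE {rse:.0f}%" if rse is not None else ""
            lines.append(f"  {label:24s} {val:10.4g}{rse_s}")
        if shr.get("CL") is not None:
            lines.append(
                f"  eta-shrinkage: CL {shr['CL']:.1f}%  V {shr['V']:.1f}%"
            )
        return "\n".join(lines)


class _Problem:
    """Packed-parameter objective with warm-started inner modes.

    Estimation-scale packing: log for positivity-constrained parameters;
    identity for power exponents; linear/categorical coefficients are
    rescaled by the largest centered covariate value seen in the data and
    boxed inside the region where every subject's covariate factor stays
    positive, which both conditions the search and removes the domain
    cliff from the optimizer's path.
    """

    def __init__(self, dataset: StudyDataset, spec: ModelSpec):
        self.spec = spec
        self.subs = []
        for s in dataset:
            if not s.observations:
                logger.warning("subject %s has no observations; excluded from fit", s.id)
                continue
            self.subs.append(_SubjData(s, spec))
        if len(self.subs) < 1:
            raise ValueError("no subjects with observations")
        self.warm = np.zeros((len(self.subs), 2))
        self.freeze_warm = False  # fixed warm starts -> objective depends on x only
        self.names = spec.param_names
        self.free = [n for n in self.names if n not in spec.fix]
        init = spec.initial_values()
        self.fixed_values = {n: init[n] for n in self.names if n in spec.fix}
        # per-parameter (scale, lo, hi) on the estimation scale
        effects = {e.name: (i, e) for i, e in enumerate(spec.effects)}
        self.scale: dict = {}
        self.bounds: list = []
        for n in self.free:
            if n in _LOG_PARAMS:
                self.scale[n] = 1.0
                self.bounds.append((-_BOUND, _BOUND))
                continue
            idx, eff = effects[n]
            if eff.form == "power":
                self.scale[n] = 1.0
                self.bounds.append((-_BOUND_POWER, _BOUND_POWER))
                continue
            d = np.concatenate([sd.eff_x[idx] for sd in self.subs])
            if eff.form == "linear":
                d = d - eff.ref
            dmax, dmin = float(d.max()), float(d.min())
            c_lo = -0.98 / dmax if dmax > 0 else -_BOUND_POWER
            c_hi = 0.98 / abs(dmin) if dmin < 0 else _BOUND_POWER
            s = max(dmax, abs(dmin), 1e-12)
            self.scale[n] = s
            self.bounds.append((c_lo * s, c_hi * s))

    def pack(self, values: dict) -> np.ndarray:
        return np.array(
            [_to_est_scale(n, values[n]) * (1.0 if n in _LOG_PARAMS else self.scale[n])
             for n in self.free]
        )

    def split(self, values: dict):
        theta = {k: v for k, v in values.items()
                 if k not in ("omega2_CL", "omega2_V", "sigma")}
        omega2 = np.array([values["omega2_CL"], values["omega2_V"]])
        return theta, omega2, values["sigma"]

    def unpack(self, x: np.ndarray) -> dict:
        values = dict(self.fixed_values)
        for name, xi in zip(self.free, x):
            if name in _LOG_PARAMS:
                values[name] = _from_est_scale(name, xi)
            else:
                values[name] = xi / self.scale[name]
        return values

    def objective(self, x: np.ndarray) -> float:
        values = self.unpack(x)
        theta, omega2, sigma = self.split(values)
        total = 0.0
        try:
            for i, sd in enumerate(self.subs):
                tvcl, tvv = sd.typical(theta)
                eta = _eta_mode(sd, tvcl, tvv, omega2, sigma, x0=self.warm[i])
                if not self.freeze_warm:
                    self.warm[i] = eta
                total += _subject_ofv(sd, tvcl, tvv, omega2, sigma, eta)
        except (ValueError, FloatingPointError, OverflowError):
            # DomainError, non-finite residuals from extreme proposals, etc.
            return 1e12
        if not math.isfinite(total):
            return 1e12
        return total


def fit_model(
    dataset: StudyDataset,
    spec: ModelSpec | None = None,
    inits: dict | None = None,
    *,
    maxiter: int = 300,
    gtol: float = 1e-3,
    verbose: bool = False,
) -> FitResult:
    """Maximum (approximate) likelihood fit of (theta, Omega, sigma).

    Minimizes :func:`foce_objective` over the packed parameter vector with
    L-BFGS-B on the estimation scale (log for CLpop, Vpop, sigma and the
    omega2; identity for covariate coefficients), refreshing each subject's
    conditional mode at every outer evaluation.  Non-convergence is flagged
    on the result, with parameters still reported; an estimate within
    ``1e-3`` of its optimizer box sets the ``boundary`` flag (used by the
    bootstrap discard rule).
    """
    if spec is None:
        spec = final_model_spec()
    if len(dataset.subjects) < 2:
        raise ValueError("fit_model requires at least 2 subjects")
    prob = _Problem(dataset, spec)
    init = spec.initial_values()
    if inits:
        init.update(inits)
    prob.fixed_values = {n: init[n] for n in prob.names if n in spec.fix}
    x0 = prob.pack(init)
    bounds = prob.bounds
    x0 = np.clip(x0, [lo for lo, _ in bounds], [hi for _, hi in bounds])
    f0 = prob.objective(x0)
    callback = None
    if verbose:
        def callback(xk):  # pragma: no cover - diagnostic aid
            print(f"[fit] ofv {prob.objective(xk):.4f}")
    res = minimize(
        prob.objective,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        callback=callback,
        options={
            "maxiter": maxiter,
            "maxfun": 40 * maxiter,
            "gtol": gtol,
            "ftol": 1e-10,
            "eps": 1e-6,
        },
    )
    values = prob.unpack(res.x)
    theta, omega2, sigma = prob.split(values)
    # refresh EBEs at the optimum
    ebes, ids = [], []
    for i, sd in enumerate(prob.subs):
        tvcl, tvv = sd.typical(theta)
        eta = _eta_mode(sd, tvcl, tvv, omega2, sigma, x0=prob.warm[i])
        prob.warm[i] = eta
        ebes.append(EtaVector(float(eta[0]), float(eta[1])))
        ids.append(sd.sid)
    boundary = any(
        min(xi - lo, hi - xi) < _BOUNDARY_TOL
        for xi, (lo, hi) in zip(res.x, bounds)
    )
    ofv = float(res.fun)
    converged = bool(res.success) and math.isfinite(ofv) and ofv <= f0 + 1e-6
    return FitResult(
        spec=spec,
        theta=theta,
        omega=OmegaMatrix(*omega2),
        sigma=SigmaSpec(sigma),
        ofv=ofv,
        ebes=ebes,
        subject_ids=ids,
        converged=converged,
        boundary=boundary,
        n_subjects=len(prob.subs),
        n_obs=sum(sd.n for sd in prob.subs),
        message=str(res.message),
    )


def eta_shrinkage(fit: FitResult) -> dict:
    """Eta-shrinkage per random effect: 100 * (1 - SD(eta_hat)/omega).

    Undefined (None) where omega = 0.
    """
    out = {}
    etas = np.array([[e.eta_cl, e.eta_v] for e in fit.ebes])
    for j, (key, w2) in enumerate(
        [("CL", fit.omega.omega2_cl), ("V", fit.omega.omega2_v)]
    ):
        if w2 <= 0:
            out[key] = None
        else:
            sd = float(np.std(etas[:, j], ddof=1)) if len(etas) > 1 else 0.0
            out[key] = 100.0 * (1.0 - sd / math.sqrt(w2))
    return out


def standard_errors(fit: FitResult, dataset: StudyDataset) -> dict:
    """Asymptotic SE/RSE% from the finite-difference Hessian of the OFV.

    The covariance of the estimates on the estimation scale is twice the
    inverse Hessian of the OFV (= -2 log L); natural-scale SEs follow by
    the delta method (log-parameters: SE_nat = estimate * SE_log).  The
    omega2 entries are reported on the CV% scale.  Returns
    ``{name: {"estimate", "se", "rse_pct"}}`` for every estimated
    parameter; values are None when the Hessian is not positive definite.
    """
    from statsmodels.tools.numdiff import approx_hess

    prob = _Problem(dataset, fit.spec)
    # seed the warm cache with the fitted EBEs for smooth evaluations
    ebe_by_id = {sid: e for sid, e in zip(fit.subject_ids, fit.ebes)}
    for i, sd in enumerate(prob.subs):
        e = ebe_by_id.get(sd.sid)
        if e is not None:
            prob.warm[i] = [e.eta_cl, e.eta_v]
    values = dict(fit.theta)
    values["omega2_CL"] = fit.omega.omega2_cl
    values["omega2_V"] = fit.omega.omega2_v
    values["sigma"] = fit.sigma.sd
    prob.fixed_values = {n: values[n] for n in prob.names if n in fit.spec.fix}
    xhat = prob.pack(values)
    prob.freeze_warm = True
    hess = approx_hess(xhat, prob.objective)
    out: dict = {}
    try:
        cov = 2.0 * np.linalg.inv(hess)
        var = np.diag(cov)
        if np.any(var <= 0):
            raise np.linalg.LinAlgError("non-positive variance")
    except np.linalg.LinAlgError:
        logger.warning("OFV Hessian not positive definite; RSEs unavailable")
        for n in prob.free:
            out[n] = {"estimate": _report_scale(n, values[n]), "se": None, "rse_pct": None}
        fit.rse_pct = {n: None for n in prob.free}
        return out
    for n, xi, v in zip(prob.free, xhat, var):
        se_t = math.sqrt(v)
        est_nat = values[n]
        if n in ("omega2_CL", "omega2_V"):
            # report on the CV% = 100*omega scale; omega = exp(x/2)
            cv = 100.0 * math.sqrt(est_nat)
            se = cv * se_t / 2.0
            out[n] = {"estimate": cv, "se": se, "rse_pct": 100.0 * se_t / 2.0}
        elif n in _LOG_PARAMS:
            se = est_nat * se_t
            out[n] = {"estimate": est_nat, "se": se, "rse_pct": 100.0 * se_t}
        else:
            se_nat = se_t / prob.scale[n]
            rse = 100.0 * se_nat / abs(est_nat) if est_nat != 0 else None
            out[n] = {"estimate": est_nat, "se": se_nat, "rse_pct": rse}
    fit.se = {n: d["se"] for n, d in out.items()}
    fit.rse_pct = {n: d["rse_pct"] for n, d in out.items()}
    return out


def _report_scale(name: str, value: float) -> float:
    if name in ("omega2_CL", "omega2_V"):
        return 100.0 * math.sqrt(value)
    return value
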
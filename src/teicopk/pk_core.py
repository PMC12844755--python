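"""Deterministic one-compartment pharmacokinetic engine for teicoplanin.

Teicoplanin disposition in adult hematological patients is described by a
one-compartment model with zero-order (constant-rate) intravenous infusion
input and first-order elimination, parameterized in clearance ``CL`` (L/h)
and volume of distribution ``V`` (L).  The population clearance model is

    CL = CLpop * (1 + th_age*(AGE - 62)) * (eGFR/92.15)**0.35 * (IBW/61)**3.2

with ideal body weight (IBW) by the Devine formula, eGFR the CKD-EPI
estimate consumed as a plain number in mL/min, and age in years.
Between-subject variability acts multiplicatively through log-normal random
effects: ``CL_i = TVCL_i * exp(eta_CL)``, ``V_i = Vpop * exp(eta_V)``.

Concentration-time curves for arbitrary multiple-infusion schedules are
computed from the closed-form single-infusion solution by superposition,
so they are exact (no ODE solver) and linear in the dose amounts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "CovariateVector",
    "ThetaSet",
    "EtaVector",
    "PKParameterSet",
    "DoseEvent",
    "Regimen",
    "devine_ibw",
    "typical_clearance",
    "individual_parameters",
    "concentration",
    "steady_state_trough",
    "expand_regimen",
    "load_regimen_library",
]

#: Default infusion length (h); teicoplanin is administered over 30 min.
DEFAULT_INFUSION_H = 0.5


def devine_ibw(height_cm: float, sex: str) -> float:
    """Ideal body weight (kg) by the Devine formula.

    ``50.0`` (men) or ``45.5`` (women) kg plus 2.3 kg per inch of height
    above 152.4 cm (5 ft), i.e. ``+ 2.3 * (height_cm - 152.4) / 2.54``.

    Parameters
    ----------
    height_cm : height in centimetres, must be positive.
    sex : ``"male"``/``"M"`` or ``"female"``/``"F"`` (case-insensitive).
    """
    if not height_cm > 0:
        raise ValueError(f"height must be positive, got {height_cm}")
    s = sex.strip().lower()
    if s in ("male", "m"):
        base = 50.0
    elif s in ("female", "f"):
        base = 45.5
    else:
        raise ValueError(f"sex must be male/female, got {sex!r}")
    return base + 2.3 * (height_cm - 152.4) / 2.54


@dataclass(frozen=True)
class CovariateVector:
    """One patient's model covariates.

    AGE in years (adults, >= 18), height HT in cm, total body weight WT in
    kg, ideal body weight IBW in kg, EGFR in mL/min (consumed as given; no
    body-surface de-indexing), serum albumin ALB in g/dL (screening only,
    optional).
    """

    AGE: float
    SEX: str
    HT: float
    WT: float
    IBW: float
    EGFR: float
    ALB: float | None = None

    def __post_init__(self) -> None:
        if self.AGE < 18:
            raise ValueError(f"adult cohort: AGE >= 18 required, got {self.AGE}")
        for name in ("HT", "WT", "IBW", "EGFR"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be positive, got {v}")

    @classmethod
    def from_height(
        cls,
        AGE: float,
        SEX: str,
        HT: float,
        WT: float,
        EGFR: float,
        ALB: float | None = None,
    ) -> "CovariateVector":
        """Build a covariate vector computing IBW from height and sex."""
        return cls(AGE=AGE, SEX=SEX, HT=HT, WT=WT,
                   IBW=devine_ibw(HT, SEX), EGFR=EGFR, ALB=ALB)

    @classmethod
    def from_ibw(
        cls,
        IBW: float,
        EGFR: float,
        AGE: float = 62.0,
        SEX: str = "male",
        ALB: float | None = None,
    ) -> "CovariateVector":
        """Virtual subject defined only by IBW (simulation strata).

        Height is back-computed from the Devine formula and total body
        weight is set equal to IBW, so per-kg doses based on either weight
        coincide for such subjects.
        """
        base = 50.0 if SEX.strip().lower() in ("male", "m") else 45.5
        ht = 152.4 + (IBW - base) * 2.54 / 2.3
        if ht <= 0:
            raise ValueError(f"IBW {IBW} infeasible for sex {SEX}")
        return cls(AGE=AGE, SEX=SEX, HT=ht, WT=IBW, IBW=IBW, EGFR=EGFR, ALB=ALB)


@dataclass(frozen=True)
class ThetaSet:
    """Fixed-effect (population) parameters of the clearance/volume model.

    Defaults are the published final estimates: CLpop 1.28 L/h, Vpop
    92.10 L, eGFR power 0.35, IBW power 3.2, age slope 0.012 /year, with
    reference covariates at the development-cohort medians (eGFR 92.15
    mL/min, IBW 61 kg, age 62 y).
    """

    CLpop: float = 1.28
    Vpop: float = 92.10
    th_egfr: float = 0.35
    th_ibw: float = 3.2
    th_age: float = 0.012
    egfr_ref: float = 92.15
    ibw_ref: float = 61.0
    age_ref: float = 62.0

    def __post_init__(self) -> None:
        for name in ("CLpop", "Vpop", "egfr_ref", "ibw_ref", "age_ref"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be positive, got {v}")

    @classmethod
    def final(cls) -> "ThetaSet":
        """The published final-model estimates (the defaults, spelled out)."""
        return cls()


@dataclass(frozen=True)
class EtaVector:
    """Subject-level random effects on CL and V (log scale)."""

    eta_cl: float = 0.0
    eta_v: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.eta_cl) and math.isfinite(self.eta_v)):
            raise ValueError("eta values must be finite")


@dataclass(frozen=True)
class PKParameterSet:
    """Individual clearance (L/h) and volume (L); ke (1/h) is derived."""

    CL: float
    V: float

    def __post_init__(self) -> None:
        if not self.CL > 0:
            raise ValueError(f"CL must be positive, got {self.CL}")
        if not self.V > 0:
            raise ValueError(f"V must be positive, got {self.V}")

    @property
    def ke(self) -> float:
        return self.CL / self.V


@dataclass(frozen=True)
class DoseEvent:
    """A single constant-rate IV infusion: start time (h), amount (mg), duration (h)."""

    time: float
    amount: float
    duration: float = DEFAULT_INFUSION_H

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"dose time must be >= 0, got {self.time}")
        if not self.amount > 0:
            raise ValueError(f"dose amount must be positive, got {self.amount}")
        if not self.duration > 0:
            raise ValueError(f"infusion duration must be positive, got {self.duration}")

    @property
    def rate(self) -> float:
        """Infusion rate R0 = amount/duration (mg/h)."""
        return self.amount / self.duration


@dataclass(frozen=True)
class Regimen:
    """A named loading-then-maintenance dosing rule.

    Doses are either fixed (mg) or weight-based (mg/kg); weight-based doses
    use total body weight by default (``dosing_weight_basis="TBW"``) with an
    IBW option.  Loading doses start at t = 0 with ``loading_interval``
    spacing; the first maintenance dose falls one ``maintenance_interval``
    after the last loading dose (so a 5 x q12h loading phase hands over to
    once-daily maintenance at t = 72 h).
    """

    loading_dose: float
    maintenance_dose: float
    loading_basis: str = "fixed"          # {"fixed", "per_kg"}
    maintenance_basis: str = "fixed"
    loading_count: int = 3
    loading_interval: float = 12.0
    maintenance_interval: float = 24.0
    dosing_weight_basis: str = "TBW"      # {"TBW", "IBW"}
    infusion_duration: float = DEFAULT_INFUSION_H

    def __post_init__(self) -> None:
        if self.loading_count < 1:
            raise ValueError("loading_count must be >= 1")
        if not (self.loading_interval > 0 and self.maintenance_interval > 0):
            raise ValueError("dosing intervals must be positive")
        if self.loading_basis not in ("fixed", "per_kg"):
            raise ValueError(f"bad loading_basis {self.loading_basis!r}")
        if self.maintenance_basis not in ("fixed", "per_kg"):
            raise ValueError(f"bad maintenance_basis {self.maintenance_basis!r}")
        if self.dosing_weight_basis not in ("TBW", "IBW"):
            raise ValueError(f"bad dosing_weight_basis {self.dosing_weight_basis!r}")


def typical_clearance(theta: ThetaSet, cov: CovariateVector) -> float:
    """Population (typical-value) clearance in L/h for given covariates.

    Implements the final covariate model: a centered linear age effect and
    power functions of eGFR and IBW normalized to the cohort medians.  At
    the reference covariates this returns ``CLpop`` exactly.

    Raises
    ------
    ValueError
        If the linear age term ``1 + th_age*(AGE - age_ref)`` is not
        positive — the model is being extrapolated outside its support and
        this is flagged rather than clamped.
    """
    age_term = 1.0 + theta.th_age * (cov.AGE - theta.age_ref)
    if not age_term > 0:
        raise ValueError(
            f"age term {age_term:.4g} <= 0 at AGE={cov.AGE}: "
            "clearance model extrapolated outside its domain"
        )
    return (
        theta.CLpop
        * age_term
        * (cov.EGFR / theta.egfr_ref) ** theta.th_egfr
        * (cov.IBW / theta.ibw_ref) ** theta.th_ibw
    )


def individual_parameters(
    theta: ThetaSet, cov: CovariateVector, eta: EtaVector = EtaVector()
) -> PKParameterSet:
    """Individual CL and V: typical values times exp(eta)."""
    return PKParameterSet(
        CL=typical_clearance(theta, cov) * math.exp(eta.eta_cl),
        V=theta.Vpop * math.exp(eta.eta_v),
    )


def _conc_arrays(
    CL: np.ndarray | float,
    V: np.ndarray | float,
    dose_t: np.ndarray,
    dose_amt: np.ndarray,
    dose_dur: np.ndarray,
    t: np.ndarray,
) -> np.ndarray:
    """Vectorized superposition kernel.

    ``CL``/``V`` may be scalars or arrays broadcastable against ``t``
    (one parameter pair per evaluation time, used for time-varying
    covariates).  Shapes: doses (m,), times (n,) -> result (n,).
    """
    CL = np.asarray(CL, dtype=float)
    V = np.asarray(V, dtype=float)
    # errstate: extreme CL/V proposed by optimizers may overflow; callers
    # treat non-finite results as out-of-domain
    with np.errstate(divide="ignore", invalid="ignore", over="ignore", under="ignore"):
        ke = CL / V
        s = t[None, :] - dose_t[:, None]                  # (m, n)
        r0_over_cl = (dose_amt / dose_dur)[:, None] / CL  # broadcasts to (m, n)
        dur = dose_dur[:, None]
        during = (s > 0) & (s <= dur)
        after = s > dur
        out = np.zeros_like(s)
        # during infusion: (R0/CL) (1 - e^{-ke s})
        out = np.where(during, r0_over_cl * -np.expm1(-ke * np.where(s > 0, s, 0.0)), out)
        # after infusion: (R0/CL) (1 - e^{-ke dur}) e^{-ke (s - dur)}
        tail = (r0_over_cl * -np.expm1(-ke * dur)
                * np.exp(-ke * np.where(after, s - dur, 0.0)))
        out = np.where(after, tail, out)
        return out.sum(axis=0)


def concentration(
    params: PKParameterSet,
    dose_events: Sequence[DoseEvent],
    t: float | Sequence[float] | np.ndarray,
) -> float | np.ndarray:
    """Plasma concentration (mg/L) at time(s) ``t`` under a dose schedule.

    Exact closed-form superposition over infusions: each dose with rate
    ``R0 = amount/duration`` contributes ``(R0/CL)(1 - e^{-ke s})`` while
    infusing and ``(R0/CL)(1 - e^{-ke dur}) e^{-ke (s - dur)}`` afterwards,
    where ``s`` is time since that dose started; doses not yet given
    contribute zero.  The result is nonnegative and linear in the amounts.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if len(dose_events) == 0:
        out = np.zeros_like(t_arr)
    else:
        dose_t = np.array([d.time for d in dose_events])
        dose_amt = np.array([d.amount for d in dose_events])
        dose_dur = np.array([d.duration for d in dose_events])
        out = _conc_arrays(params.CL, params.V, dose_t, dose_amt, dose_dur, t_arr)
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(out[0])
    return out


def steady_state_trough(
    params: PKParameterSet,
    dose_mg: float,
    tau: float,
    tinf: float = DEFAULT_INFUSION_H,
) -> float:
    """Pre-dose (trough) concentration at steady state of periodic dosing.

    Analytic accumulation formula for a repeated infusion of ``dose_mg``
    every ``tau`` h over ``tinf`` h::

        Cmin,ss = (R0/CL) (1 - e^{-ke tinf}) e^{-ke (tau - tinf)} / (1 - e^{-ke tau})

    This is the limit of :func:`concentration` under infinitely repeated
    dosing, evaluated just before a dose.
    """
    if not tinf > 0:
        raise ValueError(f"tinf must be positive, got {tinf}")
    if not tau > tinf:
        raise ValueError(f"need tau > tinf, got tau={tau}, tinf={tinf}")
    if not dose_mg > 0:
        raise ValueError(f"dose must be positive, got {dose_mg}")
    ke = params.ke
    r0 = dose_mg / tinf
    return (
        (r0 / params.CL)
        * -math.expm1(-ke * tinf)
        * math.exp(-ke * (tau - tinf))
        / -math.expm1(-ke * tau)
    )


def _dosing_weight(regimen: Regimen, cov: CovariateVector | None) -> float:
    if cov is None:
        raise ValueError("per-kg dosing requires covariates with a weight")
    return cov.IBW if regimen.dosing_weight_basis == "IBW" else cov.WT


def expand_regimen(
    regimen: Regimen,
    cov: CovariateVector | None = None,
    horizon: float = 336.0,
) -> list[DoseEvent]:
    """Expand a named regimen into explicit dose events up to ``horizon`` h.

    Loading doses at ``0, dt, ..., (n-1) dt``; maintenance doses start one
    maintenance interval after the last loading dose and repeat until the
    horizon (dose start strictly before the horizon).  Per-kg amounts are
    multiplied by the dosing weight (TBW or IBW per the regimen flag).
    """
    if regimen.loading_basis == "per_kg":
        load_amt = regimen.loading_dose * _dosing_weight(regimen, cov)
    else:
        load_amt = regimen.loading_dose
    if regimen.maintenance_basis == "per_kg":
        maint_amt = regimen.maintenance_dose * _dosing_weight(regimen, cov)
    else:
        maint_amt = regimen.maintenance_dose

    events: list[DoseEvent] = []
    for k in range(regimen.loading_count):
        tk = k * regimen.loading_interval
        if tk >= horizon:
            return events
        events.append(DoseEvent(tk, load_amt, regimen.infusion_duration))
    t_last_load = (regimen.loading_count - 1) * regimen.loading_interval
    t = t_last_load + regimen.maintenance_interval
    while t < horizon:
        events.append(DoseEvent(t, maint_amt, regimen.infusion_duration))
        t += regimen.maintenance_interval
    return events


def load_regimen_library(path: str | None = None) -> dict[str, Regimen]:
    """Load the named-regimen library from a YAML config.

    The packaged default defines the three study regimens plus the
    exploratory q12h-maintenance variant: ``smpc_6mgkg``, ``local_600``,
    ``intensified_12mgkg`` and ``intensified_12mgkg_q12maint``.
    """
    if path is None:
        text = resources.files("teicopk").joinpath("regimens.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return {name: Regimen(**kwargs) for name, kwargs in raw.items()}
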
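"""Study dataset container with NONMEM-style CSV semantics.

A :class:`StudyDataset` holds subjects, each with explicit infusion events,
trough-style concentration observations and covariates (optionally
time-varying).  On disk the dataset is a flat NONMEM-style CSV with one row
per event: dose rows (``EVID=1``, ``AMT``/``RATE`` set, ``MDV=1``) and
observation rows (``EVID=0``, ``DV`` set, ``MDV=0``), plus covariate
columns ``AGE SEX HT WT IBW EGFR ALB`` carried on every row.  SEX is coded
0 = male, 1 = female.  The round trip is lossless for all model-relevant
fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pk_core import CovariateVector, DoseEvent

__all__ = ["Observation", "Subject", "StudyDataset", "read_dataset", "write_dataset"]

_SEX_CODE = {"male": 0, "female": 1}
_SEX_DECODE = {0: "male", 1: "female"}


@dataclass(frozen=True)
class Observation:
    """One concentration measurement: time (h), DV (mg/L), BLQ flag."""

    time: float
    dv: float
    blq: bool = False

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"observation time must be >= 0, got {self.time}")


@dataclass
class Subject:
    """One subject: id, dose events, observations and covariate record(s).

    ``covariates`` is either a single :class:`CovariateVector` (constant
    covariates) or a list of ``(time, CovariateVector)`` pairs; the record
    in force at an observation is the latest one at or before its time
    (carry-forward rule).
    """

    id: int | str
    doses: list[DoseEvent]
    observations: list[Observation]
    covariates: CovariateVector | list[tuple[float, CovariateVector]]

    def __post_init__(self) -> None:
        if not self.doses:
            raise ValueError(f"subject {self.id}: at least one dose event required")
        times = [o.time for o in self.observations]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError(f"subject {self.id}: observation times must be sorted")

    def covariates_at(self, time: float) -> CovariateVector:
        """Covariate record in force at ``time`` (carry-forward)."""
        if isinstance(self.covariates, CovariateVector):
            return self.covariates
        recs = sorted(self.covariates, key=lambda tc: tc[0])
        current = recs[0][1]
        for t0, cov in recs:
            if t0 <= time:
                current = cov
            else:
                break
        return current

    @property
    def obs_times(self) -> np.ndarray:
        return np.array([o.time for o in self.observations], dtype=float)

    @property
    def dv(self) -> np.ndarray:
        return np.array([o.dv for o in self.observations], dtype=float)


@dataclass
class StudyDataset:
    """Subjects x (dose events, observations, covariates)."""

    subjects: list[Subject]

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def n_observations(self) -> int:
        return sum(len(s.observations) for s in self.subjects)

    def drop_blq(self, lloq: float = 3.0) -> tuple["StudyDataset", int]:
        """Return a copy with observations below ``lloq`` removed, and the count removed."""
        kept: list[Subject] = []
        n_dropped = 0
        for s in self.subjects:
            obs = [o for o in s.observations if not (o.blq or o.dv < lloq)]
            n_dropped += len(s.observations) - len(obs)
            kept.append(Subject(s.id, list(s.doses), obs, s.covariates))
        return StudyDataset(kept), n_dropped

    def to_frame(self) -> pd.DataFrame:
        """Flatten to a NONMEM-style event table."""
        rows = []
        for s in self.subjects:
            events: list[tuple[float, int, dict]] = []
            for d in s.doses:
                events.append((d.time, 1, {"AMT": d.amount, "RATE": d.rate}))
            for o in s.observations:
                # observations sort before a simultaneous dose (pre-dose troughs)
                events.append((o.time, 0, {"DV": o.dv}))
            events.sort(key=lambda e: (e[0], e[1]))
            for time, evid, extra in events:
                cov = s.covariates_at(time)
                row = {
                    "ID": s.id,
                    "TIME": time,
                    "AMT": extra.get("AMT", 0.0),
                    "RATE": extra.get("RATE", 0.0),
                    "DV": extra.get("DV", np.nan),
                    "EVID": evid,
                    "MDV": 1 if evid == 1 else 0,
                    "AGE": cov.AGE,
                    "SEX": _SEX_CODE[cov.SEX],
                    "HT": cov.HT,
                    "WT": cov.WT,
                    "IBW": cov.IBW,
                    "EGFR": cov.EGFR,
                    "ALB": cov.ALB if cov.ALB is not None else np.nan,
                }
                rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StudyDataset":
        required = {"ID", "TIME", "AMT", "DV", "EVID", "MDV"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing required columns: {sorted(missing)}")
        subjects = []
        for sid, grp in df.groupby("ID", sort=False):
            doses, obs = [], []
            cov_records: list[tuple[float, CovariateVector]] = []
            last_cov = None
            for idx, row in grp.iterrows():
                try:
                    cov = CovariateVector(
                        AGE=float(row["AGE"]),
                        SEX=_SEX_DECODE[int(row["SEX"])],
                        HT=float(row["HT"]),
                        WT=float(row["WT"]),
                        IBW=float(row["IBW"]),
                        EGFR=float(row["EGFR"]),
                        ALB=None if pd.isna(row.get("ALB", np.nan)) else float(row["ALB"]),
                    )
                    evid = int(row["EVID"])
                    if evid == 1:
                        amt = float(row["AMT"])
                        if "RATE" in row and row["RATE"] and not pd.isna(row["RATE"]):
                            dur = amt / float(row["RATE"])
                        elif "DUR" in row and not pd.isna(row.get("DUR", np.nan)):
                            dur = float(row["DUR"])
                        else:
                            raise ValueError("dose row needs RATE or DUR")
                        doses.append(DoseEvent(float(row["TIME"]), amt, dur))
                    elif evid == 0:
                        if int(row["MDV"]) != 0:
                            raise ValueError("observation row (EVID=0) must have MDV=0")
                        obs.append(Observation(float(row["TIME"]), float(row["DV"])))
                    else:
                        raise ValueError(f"unsupported EVID {evid}")
                except (ValueError, KeyError) as exc:
                    raise ValueError(f"malformed row {idx} (ID={sid}): {exc}") from exc
                if cov != last_cov:
                    cov_records.append((float(row["TIME"]), cov))
                    last_cov = cov
            covs: CovariateVector | list[tuple[float, CovariateVector]]
            covs = cov_records[0][1] if len(cov_records) == 1 else cov_records
            if not obs:
                import warnings

                warnings.warn(f"subject {sid} has no observations", stacklevel=2)
            subjects.append(Subject(sid, doses, sorted(obs, key=lambda o: o.time), covs))
        return cls(subjects)


def write_dataset(dataset: StudyDataset, path) -> None:
    """Write a NONMEM-style CSV (EVID=1 dose rows, EVID=0 observation rows)."""
    dataset.to_frame().to_csv(path, index=False)


def read_dataset(path) -> StudyDataset:
    """Read a NONMEM-style CSV written by :func:`write_dataset`."""
    return StudyDataset.from_frame(pd.read_csv(path))
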
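"""NONMEM-style rectangular dataset IO.

The analysis dataset is a CSV with one row per dose event or observation:

====== ======================================================================
column meaning
====== ======================================================================
ID     subject identifier (string key)
TIME   hours since the subject's first dose
EVID   1 = dose event, 0 = observation
AMT    dose amount, mg (dose rows; blank otherwise)
RATE   infusion rate, mg/h (dose rows; infusion duration = AMT/RATE)
DV     observed total serum daptomycin, mg/L (blank for dose rows and for
       below-LLOQ observations)
MDV    1 = DV missing/excluded; below-LLOQ observations carry MDV=1
WT     body weight, kg
CLCR   creatinine clearance, mL/min/1.73 m2
AGE    years
ALB    serum albumin, g/dL
SEX    M / F
STATIN 1 = statin co-administration
HT     height, m (optional)
SCR    serum creatinine, mg/dL (optional)
====== ======================================================================

Column matching is case-insensitive; extra columns are ignored on read but
the written dialect is fixed.  Observations below the 0.027 mg/L limit of
detection are written with a blank DV and MDV=1 and are excluded from the
likelihood (they carry ``below_lloq=True`` and ``dv=0.0`` in memory).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Tuple

import pandas as pd

from .pk import DoseEvent
from .population import SubjectCovariates
from .reference import LLOQ

__all__ = [
    "Observation",
    "SubjectRecord",
    "StudyDataset",
    "read_dataset",
    "write_dataset",
    "DatasetError",
]

_MANDATORY = ["ID", "TIME", "AMT", "RATE", "EVID", "DV", "MDV",
              "WT", "CLCR", "AGE", "ALB", "SEX", "STATIN"]
_COLUMNS = _MANDATORY + ["HT", "SCR"]


class DatasetError(ValueError):
    """Raised when a dataset file fails validation."""


@dataclass(frozen=True)
class Observation:
    """One serum sample: time (h), total concentration (mg/L), censoring flag."""

    time: float
    dv: float
    below_lloq: bool = False

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("observation time must be >= 0")
        if not self.below_lloq and not self.dv > 0:
            raise ValueError("observed concentration must be > 0 unless below LLOQ")


@dataclass(frozen=True)
class SubjectRecord:
    """All rows belonging to one subject."""

    id: str
    covariates: SubjectCovariates
    doses: Tuple[DoseEvent, ...]
    observations: Tuple[Observation, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "doses", tuple(self.doses))
        object.__setattr__(self, "observations", tuple(self.observations))

    @property
    def n_obs(self) -> int:
        """Number of quantifiable (non-censored) observations."""
        return sum(1 for o in self.observations if not o.below_lloq)


@dataclass(frozen=True)
class StudyDataset:
    """A collection of subject records plus free-text provenance."""

    subjects: Tuple[SubjectRecord, ...]
    provenance: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "subjects", tuple(self.subjects))
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise DatasetError("subject ids must be unique")

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def n_obs(self) -> int:
        return sum(s.n_obs for s in self.subjects)


def _num(value, row: int, col: str, required: bool) -> float:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        if required:
            raise DatasetError(f"row {row}: missing {col}")
        return math.nan
    try:
        return float(value)
    except (TypeError, ValueError):
        raise DatasetError(f"row {row}: {col}={value!r} is not numeric") from None


def read_dataset(path) -> StudyDataset:
    """Read and validate an analysis dataset CSV.

    Raises :class:`DatasetError` naming the offending row for any
    validation failure (missing mandatory column, negative TIME, dose row
    without RATE, non-positive DV on a quantifiable observation...).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [c.strip().upper() for c in df.columns]
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise DatasetError(f"missing mandatory column(s): {', '.join(missing)}")

    subjects: List[SubjectRecord] = []
    for sid, grp in df.groupby("ID", sort=False):
        doses: List[DoseEvent] = []
        obs: List[Observation] = []
        cov = None
        for idx, raw in grp.iterrows():
            row = idx + 2  # header is line 1
            time = _num(raw["TIME"], row, "TIME", required=True)
            if time < 0:
                raise DatasetError(f"row {row}: negative TIME")
            evid = int(_num(raw["EVID"], row, "EVID", required=True))
            if cov is None:
                sex = str(raw["SEX"]).strip().upper()
                if sex in ("1", "M", "MALE"):
                    sex = "M"
                elif sex in ("0", "F", "FEMALE"):
                    sex = "F"
                else:
                    raise DatasetError(f"row {row}: SEX={raw['SEX']!r} not recognised")
                ht = _num(raw.get("HT", ""), row, "HT", required=False)
                scr = _num(raw.get("SCR", ""), row, "SCR", required=False)
                cov = SubjectCovariates(
                    weight=_num(raw["WT"], row, "WT", required=True),
                    clcr=_num(raw["CLCR"], row, "CLCR", required=True),
                    age=_num(raw["AGE"], row, "AGE", required=True),
                    albumin=_num(raw["ALB"], row, "ALB", required=True),
                    sex=sex,
                    statin=bool(int(_num(raw["STATIN"], row, "STATIN", required=True))),
                    height=None if math.isnan(ht) else ht,
                    serum_creatinine=None if math.isnan(scr) else scr,
                )
            if evid == 1:
                amt = _num(raw["AMT"], row, "AMT", required=True)
                rate = _num(raw["RATE"], row, "RATE", required=True)
                if rate <= 0:
                    raise DatasetError(f"row {row}: dose row requires RATE > 0")
                doses.append(DoseEvent(start_time=time, amount=amt, duration=amt / rate))
            elif evid == 0:
                mdv = int(_num(raw["MDV"], row, "MDV", required=True))
                if mdv == 0:
                    dv = _num(raw["DV"], row, "DV", required=True)
                    if dv <= 0:
                        raise DatasetError(f"row {row}: DV must be > 0 on a "
                                           "quantifiable observation")
                    obs.append(Observation(time=time, dv=dv))
                else:
                    obs.append(Observation(time=time, dv=0.0, below_lloq=True))
            else:
                raise DatasetError(f"row {row}: EVID must be 0 or 1")
        doses.sort(key=lambda d: d.start_time)
        subjects.append(SubjectRecord(id=str(sid), covariates=cov,
                                      doses=tuple(doses), observations=tuple(obs)))
    return StudyDataset(subjects=tuple(subjects), provenance=str(path))


def _fmt(x, sig: bool = False) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    return f"{x:.6g}" if sig else repr(float(x))


def write_dataset(ds: StudyDataset, path) -> None:
    """Write a dataset in the dialect of :func:`read_dataset`.

    Deterministic column order and row order (per subject, chronological
    with observations before a dose at the same time); concentrations are
    formatted to 6 significant digits, everything else with full float
    precision so that a write/read cycle is lossless.
    """
    rows = []
    for s in ds.subjects:
        c = s.covariates
        base = {
            "ID": s.id, "WT": _fmt(c.weight), "CLCR": _fmt(c.clcr),
            "AGE": _fmt(c.age), "ALB": _fmt(c.albumin), "SEX": c.sex,
            "STATIN": str(int(c.statin)), "HT": _fmt(c.height),
            "SCR": _fmt(c.serum_creatinine),
        }
        events = [(o.time, 0, o) for o in s.observations] + \
                 [(d.start_time, 1, d) for d in s.doses]
        events.sort(key=lambda e: (e[0], e[1]))
        for time, evid, ev in events:
            row = dict(base)
            row["TIME"] = _fmt(time)
            row["EVID"] = str(evid)
            if evid == 1:
                row.update(AMT=_fmt(ev.amount), RATE=_fmt(ev.rate), DV="", MDV="1")
            else:
                row.update(AMT="", RATE="")
                if ev.below_lloq:
                    row.update(DV="", MDV="1")
                else:
                    row.update(DV=_fmt(ev.dv, sig=True), MDV="0")
            rows.append(row)
    df = pd.DataFrame(rows, columns=_COLUMNS)
    df.to_csv(path, index=False)
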
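"""Anticoagulation-quality indices computed from longitudinal INR records.

Implements the per-patient pharmacodynamic control measures used in
warfarin therapeutic-drug-monitoring studies:

* **WSI** (warfarin sensitivity index): last observed INR divided by the
  dose [mg] recorded at that visit; low values suggest warfarin
  resistance.
* **TTR** by Rosendaal linear interpolation, with the NICE threshold
  (good control iff TTR >= 65 %).
* **INR variability**: per consecutive visit pair, the squared INR change
  divided by the elapsed days and multiplied by the pair's mean INR;
  pairs are averaged, square-rooted, and log10-transformed.
* **WCM** (warfarin composite measure): cohort-standardized Z-scores of
  log-INR variability and TTR combined so that higher scores mean worse
  control (default convention z(logvar) - z(TTR); the additive
  convention z(logvar) + z(TTR) is selectable).
* Predicted liver weight: 218 + 12.3 * body weight [kg] + 51 * [male].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import numpy as np

from .errors import MetricError

__all__ = [
    "VisitRecord",
    "Patient",
    "PDIndices",
    "wsi",
    "ttr_rosendaal",
    "ttr_class",
    "inr_variability",
    "InrVariability",
    "wcm",
    "liver_weight",
    "compute_indices",
]

TTR_GOOD_THRESHOLD = 65.0  # percent; NICE classification boundary


@dataclass(frozen=True)
class VisitRecord:
    """One clinic visit: time [days from first visit], PT-INR, dose, interval."""

    patient_id: str
    t: float
    inr: float
    dose: float
    tau: float = 24.0

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError(f"visit time must be >= 0, got {self.t}")
        if not self.inr > 0:
            raise ValueError(f"INR must be > 0, got {self.inr}")
        if not self.dose > 0:
            raise ValueError(f"dose must be > 0, got {self.dose}")


@dataclass
class Patient:
    """A study participant with ordered visit history and demographics."""

    patient_id: str
    age: float
    sex: Literal["M", "F"]
    body_weight: float
    visits: list[VisitRecord] = field(default_factory=list)
    interacting_drug: bool = False

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if not self.body_weight > 0:
            raise ValueError(f"body weight must be > 0, got {self.body_weight}")
        times = [v.t for v in self.visits]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError(f"visit times not non-decreasing for {self.patient_id}")


@dataclass(frozen=True)
class PDIndices:
    """Per-patient anticoagulation-quality summary."""

    patient_id: str
    wsi: float
    ttr: float
    ttr_class: Literal["good", "poor"]
    log_inr_var: float
    wcm: float
    liver_weight: float


def wsi(patient: Patient) -> float:
    """Warfarin sensitivity index: last-visit INR / last-visit dose [INR/mg]."""
    if not patient.visits:
        raise MetricError(f"WSI needs >= 1 visit for {patient.patient_id}")
    last = patient.visits[-1]
    return last.inr / last.dose


def _segment_time_in_range(
    t0: float, t1: float, y0: float, y1: float, low: float, high: float
) -> float:
    """Time in [low, high] of the line through (t0,y0)-(t1,y1) on [t0,t1]."""
    dt = t1 - t0
    if y1 == y0:
        return dt if low <= y0 <= high else 0.0
    # times at which the line crosses each bound, clipped to the segment
    tl = t0 + (low - y0) / (y1 - y0) * dt
    th = t0 + (high - y0) / (y1 - y0) * dt
    enter, leave = sorted((tl, th))
    return max(0.0, min(leave, t1) - max(enter, t0))


def ttr_rosendaal(
    visits: Sequence[VisitRecord],
    low: float = 2.0,
    high: float = 3.0,
    max_gap_days: float | None = 56.0,
) -> float:
    """Percent time in therapeutic range by Rosendaal linear interpolation.

    The INR trajectory between consecutive visits is taken as linear; the
    fraction of the interpolated person-time with low <= INR <= high is
    returned as a percentage. Visit pairs further apart than
    ``max_gap_days`` are dropped from both numerator and denominator
    (pass ``None`` to keep all gaps).

    Raises :class:`MetricError` if fewer than two distinct visit times
    contribute person-time.
    """
    if len(visits) < 2:
        raise MetricError("TTR needs >= 2 visits")
    total = 0.0
    in_range = 0.0
    for v0, v1 in zip(visits, visits[1:]):
        dt = v1.t - v0.t
        if dt < 0:
            raise MetricError(f"visits out of order at t={v0.t} -> t={v1.t}")
        if dt == 0:
            continue
        if max_gap_days is not None and dt > max_gap_days:
            continue
        total += dt
        in_range += _segment_time_in_range(v0.t, v1.t, v0.inr, v1.inr, low, high)
    if total == 0:
        raise MetricError("TTR undefined: no usable person-time between visits")
    return 100.0 * in_range / total


def ttr_class(ttr: float) -> str:
    """NICE anticoagulation-control class: 'good' iff TTR >= 65 %."""
    return "good" if ttr >= TTR_GOOD_THRESHOLD else "poor"


class InrVariability(NamedTuple):
    sigma: float
    log10_sigma: float
    degenerate: bool  # True when all consecutive INR changes are zero


def inr_variability(visits: Sequence[VisitRecord]) -> InrVariability:
    """Time-scaled INR variability and its base-10 logarithm.

    For each consecutive visit pair i:

        v_i = (INR_{i+1} - INR_i)**2 / dt_i * (INR_i + INR_{i+1}) / 2

    sigma = sqrt(mean_i v_i), log10_sigma = log10(sigma). When every INR
    change is zero, sigma is 0 and log10 is undefined: the result carries
    ``-inf`` with ``degenerate=True`` instead of raising, so cohort code
    can exclude such patients from standardization explicitly.
    """
    if len(visits) < 2:
        raise MetricError("INR variability needs >= 2 visits")
    terms = []
    for i, (v0, v1) in enumerate(zip(visits, visits[1:])):
        dt = v1.t - v0.t
        if dt <= 0:
            raise MetricError(
                f"non-increasing times in pair {i} (t={v0.t} -> t={v1.t})"
            )
        terms.append((v1.inr - v0.inr) ** 2 / dt * (v0.inr + v1.inr) / 2.0)
    sigma = math.sqrt(sum(terms) / len(terms))
    if sigma == 0.0:
        return InrVariability(0.0, -math.inf, True)
    return InrVariability(sigma, math.log10(sigma), False)


def wcm(
    cohort_ttr: Sequence[float],
    cohort_logvar: Sequence[float],
    convention: Literal["difference", "sum"] = "difference",
) -> np.ndarray:
    """Warfarin composite measure from cohort TTR and log-INR-variability.

    Both vectors are standardized to Z-scores using the cohort sample
    mean and SD (ddof=1). Default ``difference`` convention returns
    z(logvar) - z(TTR), so higher WCM = worse control (more variable,
    less time in range); ``sum`` returns z(logvar) + z(TTR). Either way
    the cohort mean of WCM is 0 by construction.
    """
    ttr = np.asarray(cohort_ttr, dtype=float)
    logvar = np.asarray(cohort_logvar, dtype=float)
    if ttr.shape != logvar.shape or ttr.ndim != 1 or ttr.size < 2:
        raise MetricError("WCM needs two equal-length vectors of length >= 2")
    if not (np.all(np.isfinite(ttr)) and np.all(np.isfinite(logvar))):
        raise MetricError("WCM inputs must be finite (exclude degenerate patients)")
    z = []
    for name, x in (("ttr", ttr), ("log_inr_var", logvar)):
        sd = x.std(ddof=1)
        if sd == 0:
            raise MetricError(f"zero SD in {name}: Z-scores undefined")
        z.append((x - x.mean()) / sd)
    z_ttr, z_logvar = z
    if convention == "difference":
        return z_logvar - z_ttr
    if convention == "sum":
        return z_logvar + z_ttr
    raise ValueError(f"unknown WCM convention {convention!r}")


def liver_weight(body_weight: float, sex: str) -> float:
    """Predicted liver weight [g] = 218 + 12.3*weight[kg] + 51*[male]."""
    if not body_weight > 0:
        raise ValueError(f"body weight must be > 0, got {body_weight}")
    if sex not in ("M", "F"):
        raise ValueError(f"sex must be 'M' or 'F', got {sex!r}")
    return 218.0 + 12.3 * body_weight + 51.0 * (sex == "M")


def compute_indices(
    patients: Sequence[Patient],
    low: float = 2.0,
    high: float = 3.0,
    max_gap_days: float | None = 56.0,
    wcm_convention: Literal["difference", "sum"] = "difference",
):
    """Per-patient indices table for a cohort.

    Returns a pandas DataFrame with columns patient_id, wsi, ttr,
    ttr_class, log_inr_var, wcm, liver_weight. Patients whose log-INR
    variability is degenerate (all INR changes zero) get NaN WCM and are
    excluded from the WCM standardization.
    """
    import pandas as pd

    rows = []
    for pt in patients:
        var = inr_variability(pt.visits)
        t = ttr_rosendaal(pt.visits, low=low, high=high, max_gap_days=max_gap_days)
        rows.append(
            {
                "patient_id": pt.patient_id,
                "wsi": wsi(pt),
                "ttr": t,
                "ttr_class": ttr_class(t),
                "log_inr_var": var.log10_sigma,
                "liver_weight": liver_weight(pt.body_weight, pt.sex),
            }
        )
    df = pd.DataFrame(rows)
    usable = np.isfinite(df["log_inr_var"].to_numpy())
    df["wcm"] = np.nan
    if usable.sum() >= 2:
        df.loc[usable, "wcm"] = wcm(
            df.loc[usable, "ttr"], df.loc[usable, "log_inr_var"], wcm_convention
        )
    return df[
        ["patient_id", "wsi", "ttr", "ttr_class", "log_inr_var", "wcm", "liver_weight"]
    ]
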
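"""From fiducials to pulse wave velocity, and the device protocols.

Measured PWV divides the jugulum-to-thigh-cuff distance by the corrected
pulse arrival time (cPAT): the mean R-to-foot interval minus the mean
R-to-valve interval (isovolumetric contraction time), over valid beats.

The estimated-PWV protocol mirrors the clinical acquisition: three
repetitions on the same subject, each the deterministic device core
f(entered_age, MAP) plus a per-subject deviation b ~ N(0, sigma_b^2)
(drawn once per subject) and per-repetition noise e_i ~ N(0, sigma_r^2).
The entered-age experiment re-runs the protocol on one fixed subject with
the entered age swept in decades while b stays fixed (same person, same
device), then fits a quadratic of output on entered age.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import (CohortTable, ModelConstants, SubjectProfile,
                     calibrate_models, surrogate_estimated_pwv_core)
from .errors import (ImplausibleTimingError, InsufficientSignalError,
                     InvalidInputError)
from .fiducials import DetectorConfig, FiducialSet, detect_fiducials
from .signals import SignalConfig, beat_schedule, synthesize_recording

__all__ = [
    "PWVRecord",
    "EnteredAgeResult",
    "corrected_pat",
    "measured_pwv",
    "estimated_pwv_protocol",
    "entered_age_experiment",
    "run_measurement_pipeline",
]

PWV_COLUMNS = ["subject_id", "pat", "ict_hat", "cpat", "distance",
               "measured_pwv", "est_rep1", "est_rep2", "est_rep3",
               "estimated_pwv"]


@dataclass
class PWVRecord:
    """Per-subject timing and PWV summary."""

    subject_id: str
    pat: float            # s, mean R-to-foot over valid beats
    ict_hat: float        # s, mean R-to-valve
    cpat: float           # s, pat - ict_hat
    distance: float       # m
    measured_pwv: float   # m/s
    est_reps: tuple[float, float, float]
    estimated_pwv: float  # mean of the three repetitions

    def as_row(self) -> dict:
        r1, r2, r3 = self.est_reps
        return {"subject_id": self.subject_id, "pat": self.pat,
                "ict_hat": self.ict_hat, "cpat": self.cpat,
                "distance": self.distance, "measured_pwv": self.measured_pwv,
                "est_rep1": r1, "est_rep2": r2, "est_rep3": r3,
                "estimated_pwv": self.estimated_pwv}


@dataclass
class EnteredAgeResult:
    """Entered-age sweep on one subject: triplicates and the quadratic fit."""

    entered_ages: np.ndarray       # sorted grid, years
    presented_order: np.ndarray    # order in which ages were entered
    values: np.ndarray             # shape (len(grid), n_reps), m/s
    coefficients: np.ndarray       # quadratic fit [b0, b1, b2]
    r_squared: float


def corrected_pat(fiducials: FiducialSet, agg: str = "mean") -> dict:
    """PAT, estimated ICT, and corrected PAT from valid beats.

    Requires >= 3 valid beats; raises if the correction leaves a
    non-positive travel time.
    """
    valid = fiducials.valid
    if len(valid) < 3:
        raise InsufficientSignalError(
            f"only {len(valid)} valid beats, need at least 3")
    reduce = np.median if agg == "median" else np.mean
    pat = float(reduce(valid["t_foot_hat"].to_numpy() - valid["t_r_hat"].to_numpy()))
    ict_hat = float(reduce(valid["t_valve_hat"].to_numpy() - valid["t_r_hat"].to_numpy()))
    cpat = pat - ict_hat
    if cpat <= 0:
        raise ImplausibleTimingError(
            f"corrected PAT {cpat:.4f} s is not positive (pat={pat:.4f}, "
            f"ict_hat={ict_hat:.4f})")
    return {"pat": pat, "ict_hat": ict_hat, "cpat": cpat}


def measured_pwv(distance: float, cpat: float) -> float:
    """Transit-time PWV: path length divided by corrected arrival time."""
    if not (distance > 0 and cpat > 0):
        raise InvalidInputError(
            f"distance and cpat must be positive, got {distance}, {cpat}")
    return distance / cpat


def estimated_pwv_protocol(subject: SubjectProfile | pd.Series,
                           rng: np.random.Generator,
                           model: ModelConstants | None = None,
                           n_reps: int = 3,
                           subject_deviation: float | None = None
                           ) -> tuple[np.ndarray, float]:
    """Triplicate device acquisition; returns (repetitions, their mean)."""
    model = model or calibrate_models()
    core = surrogate_estimated_pwv_core(subject["entered_age"] if isinstance(subject, pd.Series)
                                        else subject.entered_age,
                                        subject["map"] if isinstance(subject, pd.Series)
                                        else subject.map, model)
    b = (rng.normal(0.0, model.sigma_b) if subject_deviation is None
         else subject_deviation)
    reps = core + b + rng.normal(0.0, model.sigma_r, n_reps)
    return reps, float(np.mean(reps))


def entered_age_experiment(base_subject: SubjectProfile | pd.Series,
                           ages, rng: np.random.Generator,
                           model: ModelConstants | None = None,
                           n_reps: int = 3,
                           subject_deviation: float | None = None
                           ) -> EnteredAgeResult:
    """Sweep the device's entered age on one fixed subject.

    The per-subject deviation b is drawn once and held fixed across entries
    (same person, same device); only per-repetition noise varies.  Ages are
    presented in random order, but repetition noise is keyed to the sorted
    grid so the fitted R^2 is invariant to the presentation order.
    """
    model = model or calibrate_models()
    grid = np.unique(np.asarray(ages, dtype=float))
    if len(grid) < 3:
        raise InvalidInputError(
            f"need >= 3 distinct entered ages, got {len(grid)}")
    subject_map = (base_subject["map"] if isinstance(base_subject, pd.Series)
                   else base_subject.map)
    b = (rng.normal(0.0, model.sigma_b) if subject_deviation is None
         else subject_deviation)
    order = rng.permutation(len(grid))
    noise = rng.normal(0.0, model.sigma_r, size=(len(grid), n_reps))
    core = surrogate_estimated_pwv_core(grid, np.full(len(grid), subject_map), model)
    values = core[:, None] + b + noise

    x = np.repeat(grid, n_reps)
    y = values.ravel()
    design = np.column_stack([np.ones_like(x), x, x**2])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean())**2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return EnteredAgeResult(entered_ages=grid, presented_order=order,
                            values=values, coefficients=coef, r_squared=float(r2))


def run_measurement_pipeline(cohort: CohortTable,
                             rng: np.random.Generator,
                             signal_config: SignalConfig | None = None,
                             detector_config: DetectorConfig | None = None,
                             model: ModelConstants | None = None,
                             via_signals: bool = True) -> pd.DataFrame:
    """Full per-subject pipeline over a cohort.

    For each subject: synthesize a recording, detect fiducials, compute
    corrected PAT and measured PWV, and run the triplicate estimation
    protocol.  With ``via_signals=False`` (or presets without a transit-time
    measurement) the measured columns are NaN and only the device protocol
    runs.  Returns a DataFrame with the PWVRecord schema plus ``age``,
    ``entered_age``, ``map``, ``sex``, ``bmi``, ``true_pwv`` carried over for
    downstream statistics.
    """
    model = model or calibrate_models()
    sig_cfg = signal_config or SignalConfig()
    det_cfg = detector_config or DetectorConfig()
    rows = []
    for subject in cohort.subjects():
        if via_signals:
            schedule = beat_schedule(subject, sig_cfg.duration, rng,
                                     jitter=sig_cfg.jitter)
            bundle = synthesize_recording(subject, rng=rng, config=sig_cfg,
                                          schedule=schedule)
            fset = detect_fiducials(bundle, det_cfg)
            timing = corrected_pat(fset)
            mpwv = measured_pwv(subject.distance, timing["cpat"])
        else:
            timing = {"pat": np.nan, "ict_hat": np.nan, "cpat": np.nan}
            mpwv = np.nan
        reps, est = estimated_pwv_protocol(subject, rng, model)
        rec = PWVRecord(subject_id=subject.subject_id, pat=timing["pat"],
                        ict_hat=timing["ict_hat"], cpat=timing["cpat"],
                        distance=subject.distance, measured_pwv=mpwv,
                        est_reps=tuple(reps[:3]), estimated_pwv=est)
        row = rec.as_row()
        row.update(age=subject.age, entered_age=subject.entered_age,
                   map=subject.map, sex=subject.sex, bmi=subject.bmi,
                   true_pwv=subject.true_pwv)
        rows.append(row)
    return pd.DataFrame(rows)
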
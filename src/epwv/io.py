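"""CSV/JSON serialization for every pipeline artifact.

Round trips preserve values to 12 significant digits; unknown columns are
kept on read with a warning, and missing schema columns raise a
:class:`~epwv.errors.FormatError` naming the column.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import COHORT_COLUMNS, CohortTable
from .errors import FormatError
from .fiducials import FIDUCIAL_COLUMNS, FiducialSet
from .pipeline import PWV_COLUMNS
from .signals import BeatAnnotation, WaveformBundle

__all__ = [
    "write_cohort", "read_cohort", "write_bundle", "read_bundle",
    "write_fiducials", "read_fiducials", "write_pwv_records",
    "read_pwv_records", "write_report_json",
]

_FLOAT_FMT = "%.12g"


def _check_columns(frame: pd.DataFrame, required: list[str], path) -> None:
    for col in required:
        if col not in frame.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    extra = [c for c in frame.columns if c not in required]
    if extra:
        warnings.warn(f"{path}: unknown columns preserved: {extra}", stacklevel=3)


def write_cohort(cohort: CohortTable, path) -> None:
    frame = cohort.frame.copy()
    frame.attrs = {}
    with open(path, "w") as fh:
        fh.write(f"# preset={cohort.preset}\n")
        fh.write(f"# seed={cohort.seed}\n")
        frame.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def _read_header_comments(path) -> dict[str, str]:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
    return meta


def read_cohort(path) -> CohortTable:
    meta = _read_header_comments(path)
    frame = pd.read_csv(path, comment="#")
    _check_columns(frame, COHORT_COLUMNS, path)
    seed = meta.get("seed")
    seed = None if seed in (None, "None") else int(seed)
    return CohortTable(frame=frame, preset=meta.get("preset", "custom"), seed=seed)


def write_bundle(bundle: WaveformBundle, path, truth_path=None) -> None:
    """Waveforms as CSV with ``# sampling_rate_hz=`` / ``# subject_id=``
    header comments; truth annotations in a sibling ``*.truth.csv``."""
    path = Path(path)
    t = bundle.time
    frame = pd.DataFrame({"t": t, **bundle.channels})
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz={bundle.sampling_rate}\n")
        fh.write(f"# subject_id={bundle.subject_id}\n")
        fh.write(f"# duration_s={bundle.duration}\n")
        frame.to_csv(fh, index=False, float_format=_FLOAT_FMT)
    truth_path = Path(truth_path) if truth_path else path.with_suffix(".truth.csv")
    truth = pd.DataFrame([{"beat_index": b.beat_index, "t_r": b.t_r,
                           "t_valve": b.t_valve, "t_foot": b.t_foot}
                          for b in bundle.truth])
    truth.to_csv(truth_path, index=False, float_format=_FLOAT_FMT)


def read_bundle(path, truth_path=None) -> WaveformBundle:
    path = Path(path)
    meta = _read_header_comments(path)
    if "sampling_rate_hz" not in meta:
        raise FormatError(f"{path}: missing '# sampling_rate_hz=' header")
    frame = pd.read_csv(path, comment="#")
    _check_columns(frame, ["t", "ecg", "doppler_env", "cuff"], path)
    fs = float(meta["sampling_rate_hz"])
    duration = float(meta.get("duration_s", len(frame) / fs))
    truth_path = Path(truth_path) if truth_path else path.with_suffix(".truth.csv")
    truth = []
    if truth_path.exists():
        tf = pd.read_csv(truth_path)
        _check_columns(tf, ["beat_index", "t_r", "t_valve", "t_foot"], truth_path)
        truth = [BeatAnnotation(int(r.beat_index), float(r.t_r),
                                float(r.t_valve), float(r.t_foot))
                 for r in tf.itertuples()]
    channels = {c: frame[c].to_numpy(dtype=float)
                for c in frame.columns if c != "t"}
    return WaveformBundle(subject_id=meta.get("subject_id", "unknown"),
                          sampling_rate=fs, duration=duration,
                          channels=channels, truth=truth)


def write_fiducials(fset: FiducialSet, path) -> None:
    frame = fset.frame.copy()
    frame.insert(0, "subject_id", fset.subject_id)
    frame = frame.rename(columns={"valid": "valid_flag"})
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_fiducials(path) -> FiducialSet:
    frame = pd.read_csv(path)
    _check_columns(frame, ["subject_id", "beat_index", "t_r_hat",
                           "t_valve_hat", "t_foot_hat", "valid_flag"], path)
    subject = frame["subject_id"].iloc[0] if len(frame) else None
    out = frame.drop(columns=["subject_id"]).rename(columns={"valid_flag": "valid"})
    return FiducialSet(frame=out, subject_id=subject)


def write_pwv_records(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_pwv_records(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _check_columns(frame, PWV_COLUMNS, path)
    return frame


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_report_json(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, cls=_NumpyEncoder)
        fh.write("\n")
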
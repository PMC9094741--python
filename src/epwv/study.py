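"""One-shot study runner tying every stage together.

``run_full_study`` executes the whole comparison for a configuration:
draw cohorts, synthesize recordings, detect fiducials, compute measured
and estimated PWV, run the statistics, the entered-age experiment, and
write a JSON report plus figures.  ``replicate_summary`` is the batch
driver that repeats a preset many times and averages the headline
statistics (grand means and mean R^2 values across replicate cohorts).

All randomness flows from one top-level seed: cohort k of a batch uses
``default_rng([seed, k])``, and within a study each stage draws from one
generator in a fixed order, so identical configurations reproduce
byte-identical numeric content.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (CohortTable, PresetSpec, calibrate_models,
                     default_presets, draw_cohort, load_presets)
from .errors import ConfigError
from .fiducials import DetectorConfig
from .io import write_cohort, write_pwv_records, write_report_json
from .pipeline import (entered_age_experiment, run_measurement_pipeline)
from .signals import SignalConfig
from .stats import (bland_altman, ks_normality, quadratic_model,
                    r_squared_age_alone)

__all__ = ["StudyConfig", "run_full_study", "replicate_summary",
           "entered_age_replicates"]

log = logging.getLogger("epwv")


@dataclass
class StudyConfig:
    """Configuration of a full study run."""

    preset_names: tuple[str, ...] = ("athletes", "agbresa")
    seed: int = 42
    replicates: int = 1
    signal: SignalConfig = field(default_factory=SignalConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    entered_age_grid: tuple[float, ...] = (30, 40, 50, 60, 70, 80)
    entered_age_subject_preset: str = "single_subject"
    out_dir: str | None = None
    save_figures: bool = True
    preset_overrides: dict = field(default_factory=dict)  # name -> {field: value}
    presets_file: str | None = None

    def resolve_presets(self) -> dict[str, PresetSpec]:
        presets = dict(default_presets())
        if self.presets_file:
            presets.update(load_presets(self.presets_file))
        out = {}
        needed = set(self.preset_names) | {self.entered_age_subject_preset}
        for name in needed:
            if name not in presets:
                raise ConfigError(f"unknown preset {name!r}")
            spec = presets[name]
            if name in self.preset_overrides:
                from dataclasses import replace
                spec = replace(spec, **self.preset_overrides[name])
            out[name] = spec
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        return out

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("preset_names", "entered_age_grid"):
            if key in raw:
                kwargs[key] = tuple(raw.pop(key))
        if "signal" in raw:
            kwargs["signal"] = SignalConfig(**raw.pop("signal"))
        if "detector" in raw:
            kwargs["detector"] = DetectorConfig(**raw.pop("detector"))
        known = {"seed", "replicates", "out_dir", "save_figures",
                 "preset_overrides", "presets_file", "entered_age_subject_preset"}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown study config keys: {sorted(bad)}")
        kwargs.update(raw)
        return cls(**kwargs)

    def content_hash(self) -> str:
        payload = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _cohort_stats(records: pd.DataFrame, measured: bool) -> dict:
    """Headline statistics for one simulated cohort."""
    out = {
        "n": len(records),
        "estimated_mean": float(records["estimated_pwv"].mean()),
        "estimated_sd": float(records["estimated_pwv"].std(ddof=1)),
        "r2_est_age": r_squared_age_alone(records["estimated_pwv"], records["age"]),
        "r2_full_est": quadratic_model(
            records["estimated_pwv"], records["age"],
            covariates=records[["map", "sex", "bmi"]]).r_squared,
        "beta_age_est": quadratic_model(
            records["estimated_pwv"], records["age"],
            covariates=records[["map", "sex", "bmi"]]).standardized_betas["age"],
    }
    if measured:
        agr = bland_altman(records["estimated_pwv"], records["measured_pwv"],
                           records["age"])
        r = np.corrcoef(records["estimated_pwv"], records["measured_pwv"])[0, 1]
        out.update({
            "measured_mean": float(records["measured_pwv"].mean()),
            "measured_sd": float(records["measured_pwv"].std(ddof=1)),
            "r2_meas_age": r_squared_age_alone(records["measured_pwv"], records["age"]),
            "mean_difference": agr.mean_difference,
            "sd_difference": agr.sd_difference,
            "diff_vs_age_slope": agr.diff_vs_age_slope,
            "r2_est_meas": float(r**2),
            "partial_r_given_age": agr.partial_r_given_age,
            "partial_p": agr.partial_p,
        })
    return out


def replicate_summary(preset: PresetSpec, n_cohorts: int, seed: int,
                      signal: SignalConfig | None = None,
                      detector: DetectorConfig | None = None,
                      via_signals: bool | None = None) -> dict:
    """Repeat a preset ``n_cohorts`` times and average the statistics.

    Cohort k uses ``default_rng([seed, k])``.  Transit-time measurement runs
    through the full signal pipeline when the preset calls for it (override
    with ``via_signals``).
    """
    use_signals = preset.measure_transit if via_signals is None else via_signals
    model = calibrate_models()
    rows = []
    for k in range(n_cohorts):
        rng = np.random.default_rng([seed, k])
        cohort = draw_cohort(preset, seed=None, rng=rng, model=model)
        records = run_measurement_pipeline(cohort, rng, signal, detector,
                                           model, via_signals=use_signals)
        rows.append(_cohort_stats(records, measured=use_signals))
    frame = pd.DataFrame(rows)
    out = {f"mean_{c}": float(frame[c].mean()) for c in frame.columns if c != "n"}
    out["n_cohorts"] = n_cohorts
    out["n_per_cohort"] = preset.n
    return out


def entered_age_replicates(n_runs: int, seed: int,
                           grid=(30, 40, 50, 60, 70, 80),
                           preset_name: str = "single_subject") -> dict:
    """Repeat the entered-age experiment; report the median (and mean) R^2."""
    preset = default_presets()[preset_name]
    r2 = []
    for k in range(n_runs):
        rng = np.random.default_rng([seed, 7000 + k])
        subject = draw_cohort(preset, seed=None, rng=rng).subjects()[0]
        res = entered_age_experiment(subject, grid, rng)
        r2.append(res.r_squared)
    r2 = np.asarray(r2)
    return {"median_r2": float(np.median(r2)), "mean_r2": float(np.mean(r2)),
            "n_runs": n_runs, "grid": list(map(float, grid))}


def _figures(results: dict, frames: dict[str, pd.DataFrame],
             entered_age, out_dir: Path) -> list[str]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    # A: estimated PWV vs age, both cohorts with quadratic fits
    fig, ax = plt.subplots(figsize=(5, 4))
    for name, frame in frames.items():
        marker = "o" if name == "athletes" else "s"
        filled = "none" if name == "athletes" else "k"
        ax.scatter(frame["age"], frame["estimated_pwv"], marker=marker,
                   facecolors=filled, edgecolors="k", s=20, label=name)
        coef = np.polyfit(frame["age"], frame["estimated_pwv"], 2)
        xs = np.linspace(frame["age"].min(), frame["age"].max(), 100)
        ax.plot(xs, np.polyval(coef, xs), lw=1)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("estimated PWV (m/s)")
    ax.legend()
    fig.tight_layout()
    p = out_dir / "fig1a.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(str(p))

    # B: difference vs age in the transit-time cohort
    meas = [f for f in frames.values() if f["measured_pwv"].notna().all()]
    if meas:
        frame = meas[0]
        diff = frame["estimated_pwv"] - frame["measured_pwv"]
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(frame["age"], diff, marker="s", color="k", s=20)
        reg = np.polyfit(frame["age"], diff, 1)
        xs = np.linspace(frame["age"].min(), frame["age"].max(), 50)
        ax.plot(xs, np.polyval(reg, xs), lw=1)
        ax.set_xlabel("age (years)")
        ax.set_ylabel("estimated - measured PWV (m/s)")
        fig.tight_layout()
        p = out_dir / "fig1b.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(str(p))

    # C: entered-age experiment
    if entered_age is not None:
        fig, ax = plt.subplots(figsize=(5, 4))
        for j in range(entered_age.values.shape[1]):
            ax.scatter(entered_age.entered_ages, entered_age.values[:, j],
                       color="k", s=18)
        xs = np.linspace(entered_age.entered_ages.min(),
                         entered_age.entered_ages.max(), 100)
        b0, b1, b2 = entered_age.coefficients
        ax.plot(xs, b0 + b1 * xs + b2 * xs**2, lw=1)
        ax.set_xlabel("entered age (years)")
        ax.set_ylabel("estimated PWV (m/s)")
        fig.tight_layout()
        p = out_dir / "fig1c.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(str(p))
    return written


def run_full_study(config: StudyConfig) -> dict:
    """Run the full comparison and return the study report (a dict).

    Pipeline order per preset: draw cohort -> synthesize -> detect -> PWV ->
    statistics; then the entered-age experiment and the report.  With an
    ``out_dir`` the report, intermediate CSVs and figures are written there.
    """
    presets = config.resolve_presets()
    model = calibrate_models()
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "provenance": {
            "seed": config.seed,
            "config_hash": config.content_hash(),
            "package_version": __version__,
            "presets": {n: asdict(presets[n]) for n in config.preset_names},
        },
        "cohorts": {},
        "regressions": [],
        "normality": {},
    }
    frames: dict[str, pd.DataFrame] = {}
    rng = np.random.default_rng([config.seed, 0])

    for name in config.preset_names:
        preset = presets[name]
        log.info("stage=draw_cohort preset=%s n=%d", name, preset.n)
        cohort = draw_cohort(preset, seed=None, rng=rng, model=model)
        log.info("stage=pipeline preset=%s", name)
        try:
            records = run_measurement_pipeline(
                cohort, rng, config.signal, config.detector, model,
                via_signals=preset.measure_transit)
        except Exception:
            log.exception("stage=pipeline preset=%s failed", name)
            raise
        frames[name] = records
        report["cohorts"][name] = _cohort_stats(records, preset.measure_transit)

        full = quadratic_model(records["estimated_pwv"], records["age"],
                               covariates=records[["map", "sex", "bmi"]],
                               outcome_name=f"{name}:estimated_pwv")
        age_only = quadratic_model(records["estimated_pwv"], records["age"],
                                   outcome_name=f"{name}:estimated_pwv(age only)")
        report["regressions"] += [full.to_dict(), age_only.to_dict()]
        report["normality"][f"{name}:estimated_pwv"] = ks_normality(
            records["estimated_pwv"])
        if preset.measure_transit:
            meas_age = quadratic_model(records["measured_pwv"], records["age"],
                                       outcome_name=f"{name}:measured_pwv(age only)")
            meas_full = quadratic_model(records["measured_pwv"], records["age"],
                                        covariates=records[["map", "sex", "bmi"]],
                                        outcome_name=f"{name}:measured_pwv")
            report["regressions"] += [meas_age.to_dict(), meas_full.to_dict()]
            report["normality"][f"{name}:measured_pwv"] = ks_normality(
                records["measured_pwv"])
            agr = bland_altman(records["estimated_pwv"],
                               records["measured_pwv"], records["age"])
            report["agreement"] = {name: agr.to_dict()}
        if out_dir:
            write_cohort(cohort, out_dir / f"cohort_{name}.csv")
            write_pwv_records(records, out_dir / f"pwv_{name}.csv")

    log.info("stage=entered_age")
    ea_preset = presets[config.entered_age_subject_preset]
    subject = draw_cohort(ea_preset, seed=None, rng=rng, model=model).subjects()[0]
    ea = entered_age_experiment(subject, config.entered_age_grid, rng, model)
    report["entered_age"] = {
        "entered_ages": ea.entered_ages.tolist(),
        "values": ea.values.tolist(),
        "coefficients": ea.coefficients.tolist(),
        "r_squared": ea.r_squared,
        "subject_age": subject.age,
    }

    if out_dir:
        if config.save_figures:
            report["figures"] = _figures(report, frames, ea, out_dir)
        write_report_json(report, out_dir / "report.json")
    return report
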
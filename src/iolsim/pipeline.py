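"""End-to-end workflows: lens-profile programming and DFVA analysis.

``program_lens`` runs the full chain from bench through-focus MTF data to
a validated temporal-multiplexing profile:

    normalize → polychromatic average → zero-phase smoothing →
    plane conversion → NNLS temporal coefficients → reconstruction →
    dwell compensation → simulated high-speed focimetry → agreement.

``analyze_dfva`` computes per-lens offsets, agreement with reference
curves, depth of focus, benefit triples and cohort statistics from
defocus visual-acuity tables.

Both have thin file-based wrappers (``run_program_lens`` /
``run_analyze_dfva``) used by the command-line interface; all outputs of
a run are deterministic so reruns are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .curves import AgreementReport, DFVACurve, TFMTFCurve, TFVSCurve, compare_curves
from .cohort import DofGainModel, omnibus_and_posthoc
from .dfva import (compute_dof, compare_to_reference, read_dfva_table)
from .multiplexing import (TemporalMultiplexModel, TemporalProfile,
                           compensate_profile, default_addition_grid,
                           reconstruct_tfvs, simulate_focimeter)
from .optics import monofocal_vs_kernel
from .synthetic import DESIGNS, make_synthetic_tfmtf
from .tfvs import (FilterSpec, convert_plane, normalize_tfmtf,
                   polychromatic_average, smooth_kernel, smooth_to_tfvs)

__all__ = [
    "ProgramLensConfig",
    "AnalyzeDfvaConfig",
    "ProgramLensResult",
    "program_lens",
    "program_lens_from_design",
    "run_program_lens",
    "analyze_dfva",
    "run_analyze_dfva",
]


class ValidationThresholds(BaseModel):
    """Printed validation bounds of the simulation chain."""

    min_cross_correlation: float = 0.982
    max_rmse: float = 0.040
    max_peak_shift_D: float = 0.2
    max_focimetry_rmse: float = 0.05


class ProgramLensConfig(BaseModel):
    """All tunables of the lens-programming workflow."""

    tfmtf_csv: list[str] = Field(default_factory=list)
    design: Optional[str] = None          # packaged synthetic design name
    pupil_mm: float = Field(3.0, gt=0)
    nu_cpd: float = Field(15.0, ge=0)
    wavelength_nm: float = Field(555.0, gt=0)
    resample_step_D: float = Field(0.05, gt=0)
    plane_factor: float = Field(1.0, gt=0)
    passband_freq: float = 0.05
    stopband_freq: float = 0.5
    passband_ripple_db: float = 0.05
    stopband_attenuation_db: float = 10.0
    addition_min_D: float = -0.5
    addition_max_D: float = 4.5
    prune_fraction: float = Field(0.01, ge=0, lt=1)
    rmse_step_tol: float = Field(0.001, ge=0)
    time_constant_ms: float = Field(1.0, ge=0)
    sample_rate_khz: float = Field(100.0, gt=0)
    compensate: bool = True
    thresholds: ValidationThresholds = Field(default_factory=ValidationThresholds)

    @model_validator(mode="after")
    def _check_input(self) -> "ProgramLensConfig":
        if self.design is not None and self.design not in DESIGNS:
            raise ValueError(f"unknown design '{self.design}'; "
                             f"choose from {sorted(DESIGNS)}")
        if self.addition_min_D >= self.addition_max_D:
            raise ValueError("addition_min_D must be below addition_max_D")
        return self

    def filter_spec(self) -> FilterSpec:
        return FilterSpec(self.passband_freq, self.stopband_freq,
                          self.passband_ripple_db, self.stopband_attenuation_db)


@dataclass
class ProgramLensResult:
    """Everything the lens-programming chain produces for one lens."""

    estimated_tfvs: TFVSCurve
    profile: TemporalProfile
    commanded_profile: TemporalProfile
    reconstructed_tfvs: TFVSCurve
    focimeter_tfvs: TFVSCurve
    reconstruction_agreement: AgreementReport
    focimetry_agreement: AgreementReport
    n_states: int
    fit_summary: str
    passed: bool

    def validation_dict(self) -> dict[str, Any]:
        return {
            "reconstruction": self.reconstruction_agreement.to_dict(),
            "focimetry": self.focimetry_agreement.to_dict(),
            "n_states": self.n_states,
            "passed": self.passed,
        }


def _focimetry_window(profile: TemporalProfile, grid: np.ndarray) -> np.ndarray:
    """Mask of the defocus range spanned by the profile's additions."""
    lo = -float(profile.additions.max())
    hi = -float(profile.additions.min())
    m = (grid >= lo - 1e-9) & (grid <= hi + 1e-9)
    return m if m.sum() >= 3 else np.ones_like(grid, dtype=bool)


def program_lens(curves: list[TFMTFCurve],
                 config: ProgramLensConfig | None = None) -> ProgramLensResult:
    """Program and validate one lens from its through-focus MTF data."""
    config = config or ProgramLensConfig()
    spec = config.filter_spec()
    avg = polychromatic_average(curves)
    est = smooth_to_tfvs(normalize_tfmtf(avg), spec, config.resample_step_D)
    est = convert_plane(est, config.plane_factor)
    additions = default_addition_grid(config.addition_min_D,
                                      config.addition_max_D,
                                      config.resample_step_D)
    # restrict the target to the defocus range the additions can reach
    lo = max(-additions.max(), float(est.defocus[0]))
    hi = min(-additions.min(), float(est.defocus[-1]))
    target = est.restrict(lo, hi)
    kernel = monofocal_vs_kernel(config.pupil_mm, config.nu_cpd,
                                 config.wavelength_nm)
    fit_kernel = smooth_kernel(kernel, spec, config.resample_step_D)
    results = TemporalMultiplexModel(target, fit_kernel, additions,
                                     config.prune_fraction,
                                     config.rmse_step_tol).fit()
    profile = results.profile
    recon_est = results.fitted_curve        # on the estimation (filtered) scale
    rec_agree = compare_curves(target, recon_est)
    # focimetry validation happens on the raw (unfiltered) reconstruction
    nominal = reconstruct_tfvs(profile, kernel, target.defocus)
    commanded = profile
    if config.compensate and config.time_constant_ms > 0:
        commanded = compensate_profile(profile, config.time_constant_ms,
                                       config.sample_rate_khz,
                                       kernel=kernel, grid=target.defocus)
    focim = simulate_focimeter(commanded, kernel, target.defocus,
                               config.time_constant_ms,
                               config.sample_rate_khz)
    win = _focimetry_window(profile, target.defocus)
    foc_agree = compare_curves(
        TFVSCurve(target.defocus[win], nominal.values[win], plane=nominal.plane),
        TFVSCurve(target.defocus[win], focim.values[win], plane=focim.plane))
    th = config.thresholds
    passed = (rec_agree.cross_correlation >= th.min_cross_correlation
              and rec_agree.rmse <= th.max_rmse
              and foc_agree.peak_shift <= th.max_peak_shift_D
              and foc_agree.rmse <= th.max_focimetry_rmse)
    return ProgramLensResult(
        estimated_tfvs=target, profile=profile, commanded_profile=commanded,
        reconstructed_tfvs=recon_est, focimeter_tfvs=focim,
        reconstruction_agreement=rec_agree, focimetry_agreement=foc_agree,
        n_states=profile.n_states, fit_summary=results.summary(),
        passed=passed)


def program_lens_from_design(name: str,
                             config: ProgramLensConfig | None = None
                             ) -> ProgramLensResult:
    """Run the lens-programming chain on a packaged synthetic design."""
    curve = make_synthetic_tfmtf(DESIGNS[name])
    return program_lens([curve], config)


# ---------------------------------------------------------------------------
# DFVA analysis
# ---------------------------------------------------------------------------

class AnalyzeDfvaConfig(BaseModel):
    """Tunables of the DFVA analysis workflow."""

    dfva_csv: Optional[str] = None
    reference_csv: Optional[str] = None
    monofocal_label: str = "monofocal"
    lens_groups: dict[str, str] = Field(default_factory=dict)
    lens_sessions: dict[str, str] = Field(default_factory=dict)
    dof_threshold: float = 0.20
    dof_range_trifocal: tuple[float, float] = (0.0, -4.0)
    dof_range_edof: tuple[float, float] = (0.0, -3.0)


def _dof_range(group: str, config: AnalyzeDfvaConfig) -> tuple[float, float]:
    return (config.dof_range_trifocal if group == "trifocal"
            else config.dof_range_edof)


def _mean_curve(curves: list[DFVACurve], label: str) -> DFVACurve:
    grid = curves[0].vergence
    ys = np.stack([np.interp(grid[::-1], c.vergence[::-1], c.logmar[::-1])[::-1]
                   for c in curves])
    return DFVACurve(grid, ys.mean(axis=0), label=label)


def analyze_dfva(curves: list[DFVACurve],
                 references: list[DFVACurve] | None = None,
                 config: AnalyzeDfvaConfig | None = None) -> dict[str, Any]:
    """Per-lens and cohort-level analysis of DFVA curves.

    ``curves`` holds per-subject (or average) curves per lens;
    ``references`` optional average curves per lens to validate against.
    """
    config = config or AnalyzeDfvaConfig()
    by_lens: dict[str, list[DFVACurve]] = {}
    for c in curves:
        by_lens.setdefault(c.label, []).append(c)
    mono_label = config.monofocal_label
    means = {lens: _mean_curve(cs, lens) for lens, cs in by_lens.items()}
    refs = {c.label: c for c in references or []}

    report: dict[str, Any] = {"lenses": {}, "cohort": {}}
    metric_rows = []
    for lens, cs in by_lens.items():
        group = config.lens_groups.get(lens, "EDOF")
        entry: dict[str, Any] = {"n_curves": len(cs), "group": group}
        if lens in refs:
            entry["reference"] = compare_to_reference(means[lens],
                                                      refs[lens]).to_dict()
        rng = _dof_range(group, config)
        entry["dof_mean"] = float(np.mean(
            [compute_dof(c, config.dof_threshold, rng) for c in cs]))
        report["lenses"][lens] = entry
        if lens == mono_label:
            continue
        mono_by_subject = {c.subject_id: c for c in by_lens.get(mono_label, [])}
        for c in cs:
            mono = mono_by_subject.get(c.subject_id)
            if mono is None:
                continue
            row: dict[str, Any] = {
                "subject": c.subject_id, "lens": lens, "group": group,
                "session": config.lens_sessions.get(lens, "I"),
                "dof": compute_dof(c, config.dof_threshold, rng),
                "baseline_dof": compute_dof(mono, config.dof_threshold, rng),
            }
            for name, d in (("far", 0.0), ("intermediate", -1.5),
                            ("near", -2.5)):
                try:
                    row[name] = mono.value_at(d) - c.value_at(d)
                except KeyError:
                    warnings.warn(f"no {d:+.2f} D measurement for "
                                  f"{lens}/{c.subject_id}: {name} benefit "
                                  "unavailable", stacklevel=2)
                    row[name] = np.nan
            metric_rows.append(row)

    if metric_rows:
        metrics = pd.DataFrame(metric_rows)
        report["subject_metrics"] = metrics.to_dict(orient="records")
        gains = metrics.assign(gain=metrics["dof"] - metrics["baseline_dof"])
        report["cohort"]["mean_dof_gain_by_group"] = {
            g: float(v) for g, v in gains.groupby("group")["gain"].mean().items()}
        try:
            fit = DofGainModel(metrics).fit()
            report["cohort"]["dof_gain_regression"] = {
                "slopes": fit.slopes,
                "interaction_pvalue": fit.interaction_pvalue,
                "session_pvalue": fit.session_pvalue,
            }
        except (ValueError, KeyError) as exc:
            report["cohort"]["dof_gain_regression"] = {"skipped": str(exc)}
        posthoc_rows = []
        for session, sess_df in metrics.groupby("session"):
            for distance in ("far", "intermediate", "near"):
                sub = sess_df.dropna(subset=[distance])
                try:
                    res = omnibus_and_posthoc(sub, distance)
                except ValueError:
                    continue
                posthoc_rows.extend(res.to_records(str(session), distance))
        report["cohort"]["posthoc"] = posthoc_rows
    return report


# ---------------------------------------------------------------------------
# file-based runners (used by the CLI)
# ---------------------------------------------------------------------------

def _jsonify(obj):
    """JSON-safe copy: numpy scalars to python, NaN to null."""
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return None if not np.isfinite(obj) else float(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _manifest(inputs: list[Path], config: BaseModel, seed: int | None,
              outputs: list[str]) -> dict[str, Any]:
    return {
        "iolsim_version": __version__,
        "inputs": {str(p): _sha256(p) for p in inputs},
        "config": json.loads(config.model_dump_json()),
        "seed": seed,
        "outputs": outputs,
    }


def _overlay_plot(result: ProgramLensResult, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    t = result.estimated_tfvs
    ax.plot(t.defocus, t.values, "k-", lw=2, label="estimated TFVS")
    r = result.reconstructed_tfvs
    ax.plot(r.defocus, r.values, "-", color="tab:blue", label="multiplexed TFVS")
    f = result.focimeter_tfvs
    ax.plot(f.defocus, f.values, "--", color="tab:orange",
            label="focimeter TFVS")
    ax.set_xlabel("defocus (D)")
    ax.set_ylabel("visual Strehl ratio")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_program_lens(config: ProgramLensConfig, out_dir: str | Path,
                     seed: int | None = None, plot: bool = True) -> bool:
    """File-based lens programming; returns True when validation passed.

    All inputs are read and the whole computation finishes before any
    output is written, so a failing run leaves no partial outputs.
    """
    inputs = [Path(p) for p in config.tfmtf_csv]
    curves: list[TFMTFCurve] = []
    for p in inputs:
        curves.extend(TFMTFCurve.from_csv(p, nu=config.nu_cpd,
                                          pupil_diameter=config.pupil_mm))
    if config.design is not None:
        curves.append(make_synthetic_tfmtf(DESIGNS[config.design]))
    if not curves:
        raise ValueError("no input curves: give tfmtf_csv or design")
    result = program_lens(curves, config)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs = ["profile.json", "validation.json", "estimated_tfvs.csv"]
    if plot:
        outputs.append("tfvs_overlay.png")
    result.profile.to_json(out / "profile.json")
    with open(out / "validation.json", "w") as fh:
        json.dump(result.validation_dict(), fh, indent=2)
    result.estimated_tfvs.to_csv(out / "estimated_tfvs.csv")
    if plot:
        _overlay_plot(result, out / "tfvs_overlay.png")
    with open(out / "manifest.json", "w") as fh:
        json.dump(_manifest(inputs, config, seed, outputs), fh, indent=2)
    return result.passed


def _dfva_plot(curves_by_lens: dict[str, DFVACurve], path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for lens, c in curves_by_lens.items():
        ax.plot(c.vergence, c.logmar, marker="o", ms=3, label=lens)
    ax.invert_yaxis()
    ax.set_xlabel("vergence (D)")
    ax.set_ylabel("logMAR")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_analyze_dfva(config: AnalyzeDfvaConfig, out_dir: str | Path,
                     seed: int | None = None, plot: bool = True) -> dict[str, Any]:
    """File-based DFVA analysis; writes metrics JSON and plots."""
    if config.dfva_csv is None:
        raise ValueError("dfva_csv is required")
    inputs = [Path(config.dfva_csv)]
    curves = read_dfva_table(config.dfva_csv)
    references = None
    if config.reference_csv:
        inputs.append(Path(config.reference_csv))
        references = read_dfva_table(config.reference_csv)
    report = analyze_dfva(curves, references, config)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs = ["metrics.json"]
    with open(out / "metrics.json", "w") as fh:
        json.dump(_jsonify(report), fh, indent=2)
    if plot:
        by_lens: dict[str, list[DFVACurve]] = {}
        for c in curves:
            by_lens.setdefault(c.label, []).append(c)
        means = {lens: _mean_curve(cs, lens) for lens, cs in by_lens.items()}
        _dfva_plot(means, out / "dfva_curves.png")
        outputs.append("dfva_curves.png")
    with open(out / "manifest.json", "w") as fh:
        json.dump(_manifest(inputs, config, seed, outputs), fh, indent=2)
    return report
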
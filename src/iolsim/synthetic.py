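"""Synthetic lens designs and subject cohorts.

Everything in the package can be exercised without any external data:
:func:`make_synthetic_tfmtf` builds through-focus MTF curves of stylized
monofocal, trifocal and EDOF designs (add powers follow the commercial
designs the simulator targets: trifocals with intermediate/near adds of
+2.17/+3.25, +1.75/+3.5 and +1.66/+3.33 D; EDOFs with a single
intermediate add of +1.53 to +1.9 D), and :func:`make_synthetic_cohort`
draws per-subject defocus-acuity curves around a lens template with the
intersubject variability observed clinically (residual sd ≈ 0.11 logMAR).

These are stylized emulations for testing: Gaussian focal peaks /
smoothed plateaus for the optics, and an affine template mapping plus
Gaussian subject effects for the acuity data.  They reproduce the
*structure* the analysis assumes, not any individual commercial lens or
patient cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .curves import DFVACurve, TFMTFCurve, TFVSCurve
from .dfva import DEFAULT_VERGENCE_GRID

__all__ = [
    "IOLDesignSpec",
    "CohortSpec",
    "DESIGNS",
    "ACCEPTANCE_DESIGNS",
    "make_synthetic_tfmtf",
    "make_synthetic_cohort",
    "make_dof_gain_records",
    "default_tfmtf_grid",
]


@dataclass(frozen=True)
class IOLDesignSpec:
    """Stylized optical design of an intraocular lens.

    ``add_powers`` are diopters of extra power (positive toward near); a
    peak for add ``a`` sits at defocus ``−a`` on the vergence axis.
    Trifocals carry exactly two adds besides far; EDOFs one intermediate
    add, realised either as two merged peaks (diffractive) or as a
    smoothed plateau (refractive, ``plateau=True``).
    """

    name: str
    design: str  # 'monofocal' | 'trifocal' | 'edof'
    add_powers: tuple[float, ...] = ()
    peak_width: float = 0.30          # Gaussian sigma, diopters
    relative_peak_heights: tuple[float, ...] = ()
    plateau: bool = False
    peak_mtf: float = 0.42            # raw bench MTF at the best focus

    def __post_init__(self) -> None:
        if self.design not in ("monofocal", "trifocal", "edof"):
            raise ValueError("design must be monofocal, trifocal or edof")
        if any(a < 0 for a in self.add_powers):
            raise ValueError("add powers must be >= 0")
        if self.design == "trifocal" and len(self.add_powers) != 2:
            raise ValueError("a trifocal needs exactly 2 adds besides far")
        if self.design == "edof" and len(self.add_powers) != 1:
            raise ValueError("an EDOF needs exactly 1 intermediate add")
        if self.design == "monofocal" and self.add_powers:
            raise ValueError("a monofocal has no adds")


#: Packaged design-class fixtures (adds of the six commercial targets).
DESIGNS: dict[str, IOLDesignSpec] = {
    "monofocal": IOLDesignSpec("monofocal", "monofocal"),
    "trifocal_a": IOLDesignSpec("trifocal_a", "trifocal", (2.17, 3.25),
                                relative_peak_heights=(1.0, 0.70, 0.85)),
    "trifocal_b": IOLDesignSpec("trifocal_b", "trifocal", (1.75, 3.5),
                                relative_peak_heights=(1.0, 0.75, 0.85)),
    "trifocal_c": IOLDesignSpec("trifocal_c", "trifocal", (1.66, 3.33),
                                relative_peak_heights=(1.0, 0.72, 0.80)),
    "edof_diffractive_a": IOLDesignSpec("edof_diffractive_a", "edof", (1.75,),
                                        peak_width=0.45,
                                        relative_peak_heights=(1.0, 0.85)),
    "edof_refractive": IOLDesignSpec("edof_refractive", "edof", (1.53,),
                                     plateau=True),
    "edof_diffractive_b": IOLDesignSpec("edof_diffractive_b", "edof", (1.9,),
                                        peak_width=0.45,
                                        relative_peak_heights=(1.0, 0.80)),
}

#: The five designs the lens-programming validation runs end to end.
ACCEPTANCE_DESIGNS = ("monofocal", "trifocal_b", "trifocal_a",
                      "edof_diffractive_a", "edof_diffractive_b")


def default_tfmtf_grid(lo: float = -6.0, hi: float = 2.0,
                       step: float = 0.05) -> np.ndarray:
    return np.round(np.arange(lo, hi + 1e-9, step), 10)


def _gauss(grid: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((grid - center) / sigma) ** 2)


def make_synthetic_tfmtf(spec: IOLDesignSpec, grid: np.ndarray | None = None,
                         wavelength: float | str = "white",
                         chromatic_shift: float = 0.0) -> TFMTFCurve:
    """Deterministic through-focus MTF of a stylized design.

    Multifocals are sums of Gaussian focal peaks at 0 and −add; a
    refractive EDOF is a smoothed plateau from 0 to −add.
    ``chromatic_shift`` displaces the whole curve along the defocus axis
    (to emulate per-wavelength bench data).
    """
    g = default_tfmtf_grid() if grid is None else np.asarray(grid, dtype=float)
    centers = [0.0] + [-a for a in spec.add_powers]
    if len(centers) > 1:
        gaps = np.diff(sorted(centers))
        if np.any(np.abs(gaps) < spec.peak_width):
            warnings.warn("add powers closer than one peak width: peaks merge",
                          stacklevel=2)
    x = g - chromatic_shift
    if spec.design == "edof" and spec.plateau:
        # box extends ~1.6 smoothing widths beyond the nominal plateau so
        # the plateau interior stays within 10% of the maximum
        sigma = 0.25
        margin = 1.6 * sigma
        box = ((x <= margin) & (x >= -spec.add_powers[0] - margin)).astype(float)
        step = float(np.diff(g).mean())
        vals = gaussian_filter1d(box, sigma / step)
    else:
        heights = (spec.relative_peak_heights
                   or tuple([1.0] * len(centers)))
        if len(heights) != len(centers):
            raise ValueError("one relative height per focal peak required")
        vals = np.zeros_like(x)
        for c, h in zip(centers, heights):
            vals += h * _gauss(x, c, spec.peak_width)
    vals = spec.peak_mtf * vals / vals.max()
    return TFMTFCurve(g, np.clip(vals, 0.0, None), wavelength=wavelength)


@dataclass(frozen=True)
class CohortSpec:
    """Synthetic subject cohort parameters.

    ``residual_sd`` is the independent per-measurement logMAR noise
    (default 0.11, the intersubject spread reported for simulator-measured
    acuity); ``intercept_sd`` the between-subject acuity offset.
    """

    n_subjects: int = 15
    vergence_grid: np.ndarray = field(
        default_factory=lambda: DEFAULT_VERGENCE_GRID.copy())
    residual_sd: float = 0.11
    intercept_sd: float = 0.05
    logmar_range: tuple[float, float] = (-0.1, 0.8)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if self.residual_sd < 0 or self.intercept_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")


def dfva_template(tfvs: TFVSCurve, vergence_grid: np.ndarray,
                  logmar_range: tuple[float, float] = (-0.1, 0.8)) -> np.ndarray:
    """Map a TFVS curve onto a deterministic logMAR template.

    Affine, monotone-decreasing map of the (peak-normalized) visual
    Strehl onto the logMAR range: best optical quality → best acuity.
    """
    v = np.asarray(vergence_grid, dtype=float)
    tf = np.interp(v[::-1], tfvs.defocus, tfvs.values)[::-1]
    tf = tf / tf.max() if tf.max() > 0 else tf
    lo, hi = logmar_range
    return lo + (hi - lo) * (1.0 - tf)


def make_synthetic_cohort(spec: CohortSpec,
                          lens_tfvs: dict[str, TFVSCurve],
                          lens_groups: dict[str, str] | None = None,
                          lens_sessions: dict[str, str] | None = None
                          ) -> pd.DataFrame:
    """Per-subject DFVA table for each lens profile.

    Each subject's curve is the lens template plus a subject random
    intercept plus independent residual noise.  Deterministic given the
    spec's seed.  Returns tidy rows ``subject_id,lens,group,session,
    vergence_D,logmar``.
    """
    rng = np.random.default_rng(spec.seed)
    v = spec.vergence_grid
    templates = {lens: dfva_template(c, v, spec.logmar_range)
                 for lens, c in lens_tfvs.items()}
    rows = []
    for s in range(spec.n_subjects):
        sid = f"S{s + 1:02d}"
        intercept = rng.normal(0.0, spec.intercept_sd)
        for lens, tmpl in templates.items():
            noise = rng.normal(0.0, spec.residual_sd, size=v.size)
            y = tmpl + intercept + noise
            for vi, yi in zip(v, y):
                rows.append({
                    "subject_id": sid, "lens": lens,
                    "group": (lens_groups or {}).get(lens, ""),
                    "session": (lens_sessions or {}).get(lens, ""),
                    "vergence_D": vi, "logmar": yi,
                })
    df = pd.DataFrame(rows)
    df.attrs["seed"] = spec.seed
    return df


def cohort_curves(table: pd.DataFrame) -> list[DFVACurve]:
    """Tidy cohort table → list of per-subject DFVACurve objects."""
    out = []
    for (sid, lens), sub in table.groupby(["subject_id", "lens"]):
        out.append(DFVACurve(sub["vergence_D"].to_numpy(),
                             sub["logmar"].to_numpy(),
                             label=str(lens), subject_id=str(sid)))
    return out


def make_dof_gain_records(n_subjects: int = 15,
                          slope_trifocal: float = -0.96,
                          slope_edof: float = -0.57,
                          intercept_trifocal: float = 2.9,
                          intercept_edof: float = 1.8,
                          baseline_range: tuple[float, float] = (1.0, 2.5),
                          residual_sd: float = 0.2,
                          subject_sd: float = 0.15,
                          seed: int | None = None) -> pd.DataFrame:
    """Subject-metrics table with planted baseline–gain slopes.

    Three trifocal and three EDOF lenses per subject, split across two
    sessions as in a two-visit protocol; gains follow
    ``intercept + slope·baseline + subject effect + noise``.  Used to
    validate that the mixed-effects regression recovers known effects.
    """
    rng = np.random.default_rng(seed)
    lens_layout = [("T1", "trifocal", "I"), ("T2", "trifocal", "I"),
                   ("T3", "trifocal", "II"), ("E1", "EDOF", "I"),
                   ("E2", "EDOF", "II"), ("E3", "EDOF", "II")]
    rows = []
    for s in range(n_subjects):
        baseline = rng.uniform(*baseline_range)
        u = rng.normal(0.0, subject_sd)
        for lens, group, session in lens_layout:
            slope = slope_trifocal if group == "trifocal" else slope_edof
            icept = intercept_trifocal if group == "trifocal" else intercept_edof
            gain = icept + slope * baseline + u + rng.normal(0.0, residual_sd)
            rows.append({"subject": f"S{s + 1:02d}", "lens": lens,
                         "group": group, "session": session,
                         "baseline_dof": baseline,
                         "dof": baseline + gain})
    return pd.DataFrame(rows)
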
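"""Defocus visual-acuity (DFVA) curve analytics.

Offset alignment between simulated and reference curves, agreement
metrics, depth of focus, and visual benefit/degradation relative to a
monofocal reference.

Sign conventions follow clinical usage: lower logMAR is better acuity;
benefit = monofocal logMAR − multifocal logMAR, so positive values favour
the multifocal lens and negative values indicate degradation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import AgreementReport, DFVACurve, compare_curves

__all__ = [
    "DEFAULT_VERGENCE_GRID",
    "BenefitTriple",
    "ReferenceComparison",
    "estimate_offset",
    "compute_dof",
    "visual_benefit",
    "compare_to_reference",
    "read_dfva_table",
    "write_dfva_table",
]

#: Clinical defocus grid: +1.00 to −4.00 D in 0.50 D steps.
DEFAULT_VERGENCE_GRID = np.round(np.arange(1.0, -4.0 - 1e-9, -0.5), 10)

FAR_D, INTERMEDIATE_D, NEAR_D = 0.0, -1.5, -2.5


@dataclass(frozen=True)
class BenefitTriple:
    """logMAR differences (monofocal − multifocal) at the three distances.

    ``far`` at 0 D, ``intermediate`` at −1.50 D, ``near`` at −2.50 D.
    Positive = multifocal better; negative = monofocal better.
    """

    far: float
    intermediate: float
    near: float

    def to_dict(self) -> dict[str, float]:
        return {"far": self.far, "intermediate": self.intermediate,
                "near": self.near}


def _common(sim: DFVACurve, ref: DFVACurve) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reference interpolated onto the simulated grid, common support only."""
    lo = max(sim.vergence.min(), ref.vergence.min())
    hi = min(sim.vergence.max(), ref.vergence.max())
    m = (sim.vergence >= lo - 1e-9) & (sim.vergence <= hi + 1e-9)
    v = sim.vergence[m]
    if v.size < 3:
        raise ValueError("fewer than 3 common vergences")
    ref_i = np.interp(v[::-1], ref.vergence[::-1], ref.logmar[::-1])[::-1]
    return v, sim.logmar[m], ref_i


def estimate_offset(simulated: DFVACurve, reference: DFVACurve) -> float:
    """Additive logMAR offset minimizing the RMSE between the curves.

    The minimizer has the closed form mean(reference − simulated) over the
    common vergences; applying it to the simulated curve changes its level
    but not its shape.
    """
    _, sim_y, ref_y = _common(simulated, reference)
    return float(np.mean(ref_y - sim_y))


def compute_dof(curve: DFVACurve, threshold: float = 0.20,
                range_limits: tuple[float, float] = (0.0, -3.0)) -> float:
    """Depth of focus: dioptric measure where logMAR is better than ``threshold``.

    The curve is linearly interpolated between grid points; the result is
    the total length of all sub-intervals of ``range_limits`` (intersected
    with the measured support) on which logMAR < threshold, so bimodal
    curves that re-cross the criterion contribute every compliant
    sub-interval.  The inequality is strict: stretches exactly at the
    threshold do not count.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    hi, lo = max(range_limits), min(range_limits)
    v = curve.vergence[::-1]          # ascending
    y = curve.logmar[::-1]
    lo = max(lo, float(v[0]))
    hi = min(hi, float(v[-1]))
    if hi <= lo:
        return 0.0
    # knots: grid points inside the range plus interpolated endpoints
    inner = v[(v > lo) & (v < hi)]
    knots = np.concatenate([[lo], inner, [hi]])
    vals = np.interp(knots, v, y)
    total = 0.0
    for i in range(knots.size - 1):
        x0, x1 = knots[i], knots[i + 1]
        y0, y1 = vals[i], vals[i + 1]
        seg = x1 - x0
        b0, b1 = y0 < threshold, y1 < threshold
        if b0 and b1:
            total += seg
        elif b0 != b1:
            # single crossing within the segment (linear)
            t = (threshold - y0) / (y1 - y0)
            total += seg * (t if b0 else (1.0 - t))
        # else: neither endpoint below; a linear segment cannot dip below
    return float(total)


def visual_benefit(mono: DFVACurve, miol: DFVACurve) -> BenefitTriple:
    """Benefit/degradation of a multifocal relative to the monofocal.

    Requires exact measurements at 0, −1.50 and −2.50 D (no extrapolation).
    """
    vals = {}
    for name, d in (("far", FAR_D), ("intermediate", INTERMEDIATE_D),
                    ("near", NEAR_D)):
        vals[name] = mono.value_at(d) - miol.value_at(d)
    return BenefitTriple(**vals)


@dataclass
class ReferenceComparison:
    """Offset-corrected agreement of a simulated curve with a reference."""

    offset: float
    agreement: AgreementReport
    vergences: np.ndarray
    differences: np.ndarray  # reference − offset-corrected simulated

    def to_dict(self) -> dict:
        return {
            "offset_logmar": self.offset,
            **self.agreement.to_dict(),
            "per_vergence_differences": {
                f"{v:+.2f}": float(d)
                for v, d in zip(self.vergences, self.differences)
            },
        }


def compare_to_reference(simulated: DFVACurve,
                         reference: DFVACurve) -> ReferenceComparison:
    """Offset-align the simulated curve to the reference, then compare.

    The offset is applied to the simulated curve only (the reference is
    never moved), ensuring the agreement metrics describe curve shape
    rather than baseline level.  The per-vergence differences are
    reference minus offset-corrected simulated.
    """
    offset = estimate_offset(simulated, reference)
    corrected = simulated.shifted(offset)
    agreement = compare_curves(corrected, reference)
    v, sim_y, ref_y = _common(corrected, reference)
    return ReferenceComparison(offset=offset, agreement=agreement,
                               vergences=v, differences=ref_y - sim_y)


def read_dfva_table(path) -> list[DFVACurve]:
    """Read curves from a ``subject_id,lens,vergence_D,logmar`` CSV.

    ``subject_id`` may be empty/absent for average (group-level) curves.
    """
    df = pd.read_csv(path)
    if not {"lens", "vergence_D", "logmar"}.issubset(df.columns):
        raise ValueError("DFVA CSV must have columns lens,vergence_D,logmar")
    if "subject_id" not in df.columns:
        df["subject_id"] = ""
    curves = []
    for (sid, lens), sub in df.groupby(["subject_id", "lens"], dropna=False):
        curves.append(DFVACurve(sub["vergence_D"].to_numpy(),
                                sub["logmar"].to_numpy(), label=str(lens),
                                subject_id=str(sid) if str(sid) else None))
    return curves


def write_dfva_table(curves: list[DFVACurve], path) -> None:
    rows = []
    for c in curves:
        for v, y in zip(c.vergence, c.logmar):
            rows.append({"subject_id": c.subject_id or "", "lens": c.label,
                         "vergence_D": v, "logmar": y})
    pd.DataFrame(rows).to_csv(path, index=False)
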
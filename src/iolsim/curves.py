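"""Curve containers shared across the package.

Axis conventions
----------------
Through-focus axes are in diopters with the far focus at 0 D and *near*
demands at negative values (vergence convention).  ``TFMTFCurve`` holds
bench modulation-transfer data at a single spatial frequency;
``TFVSCurve`` holds the estimated through-focus visual Strehl ratio
derived from it; ``DFVACurve`` holds measured (or simulated) logMAR
visual acuity on the clinical defocus grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "TFMTFCurve",
    "TFVSCurve",
    "DFVACurve",
    "AgreementReport",
    "compare_curves",
]


def _as_float_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise ValueError("expected a 1-D array")
    return a


@dataclass
class TFMTFCurve:
    """Through-focus MTF at one spatial frequency for one wavelength.

    Parameters
    ----------
    defocus : array of diopters (IOL plane, signed, strictly increasing)
    values : MTF ratio at the spatial frequency ``nu`` (>= 0)
    nu : spatial frequency in cycles/degree (default 15)
    wavelength : wavelength in nm, or ``"white"`` for broadband sources
        (treated as 555 nm wherever a wavelength is needed)
    pupil_diameter : pupil diameter in mm at the IOL plane (default 3.0)
    """

    defocus: np.ndarray
    values: np.ndarray
    nu: float = 15.0
    wavelength: float | str = 555.0
    pupil_diameter: float = 3.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.defocus = _as_float_array(self.defocus)
        self.values = _as_float_array(self.values)
        if self.defocus.size != self.values.size:
            raise ValueError("defocus and values must have equal length")
        if self.defocus.size < 2:
            raise ValueError("need at least 2 samples")
        if not np.all(np.diff(self.defocus) > 0):
            raise ValueError("defocus grid must be strictly increasing")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("MTF values must be finite and >= 0")
        if self.pupil_diameter <= 0:
            raise ValueError("pupil diameter must be positive")

    @property
    def wavelength_nm(self) -> float:
        """Numeric wavelength; broadband ('white') sources map to 555 nm."""
        if isinstance(self.wavelength, str):
            return 555.0
        return float(self.wavelength)

    def resample(self, grid: np.ndarray) -> "TFMTFCurve":
        """Linear interpolation onto ``grid`` (must lie within support)."""
        grid = _as_float_array(grid)
        if grid.min() < self.defocus[0] - 1e-9 or grid.max() > self.defocus[-1] + 1e-9:
            raise ValueError("resample grid extends beyond curve support")
        vals = np.interp(grid, self.defocus, self.values)
        return replace(self, defocus=grid, values=vals)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"defocus_D": self.defocus, "value": self.values})
        if not isinstance(self.wavelength, str):
            df["wavelength_nm"] = self.wavelength
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **kwargs) -> list["TFMTFCurve"]:
        """Read one curve per wavelength from ``defocus_D,value[,wavelength_nm]``."""
        df = pd.read_csv(path)
        required = {"defocus_D", "value"}
        if not required.issubset(df.columns):
            raise ValueError(f"TF-MTF CSV must have columns {sorted(required)}")
        out = []
        if "wavelength_nm" in df.columns:
            for wl, sub in df.groupby("wavelength_nm"):
                sub = sub.sort_values("defocus_D")
                out.append(cls(sub["defocus_D"].to_numpy(), sub["value"].to_numpy(),
                               wavelength=float(wl), **kwargs))
        else:
            df = df.sort_values("defocus_D")
            out.append(cls(df["defocus_D"].to_numpy(), df["value"].to_numpy(), **kwargs))
        return out


@dataclass
class TFVSCurve:
    """Estimated through-focus visual Strehl ratio versus defocus."""

    defocus: np.ndarray
    values: np.ndarray
    plane: str = "IOL"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.defocus = _as_float_array(self.defocus)
        self.values = _as_float_array(self.values)
        if self.defocus.size != self.values.size:
            raise ValueError("defocus and values must have equal length")
        if not np.all(np.diff(self.defocus) > 0):
            raise ValueError("defocus grid must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if self.plane not in ("IOL", "entrance_pupil"):
            raise ValueError("plane must be 'IOL' or 'entrance_pupil'")

    @property
    def step(self) -> float:
        d = np.diff(self.defocus)
        if not np.allclose(d, d[0], atol=1e-9):
            raise ValueError("grid is not uniform")
        return float(d[0])

    def restrict(self, lo: float, hi: float) -> "TFVSCurve":
        m = (self.defocus >= lo - 1e-9) & (self.defocus <= hi + 1e-9)
        if m.sum() < 2:
            raise ValueError("restriction leaves fewer than 2 samples")
        return replace(self, defocus=self.defocus[m], values=self.values[m])

    def resample(self, grid: np.ndarray) -> "TFVSCurve":
        grid = _as_float_array(grid)
        vals = np.interp(grid, self.defocus, self.values)
        return replace(self, defocus=grid, values=vals)

    def to_csv(self, path) -> None:
        pd.DataFrame({"defocus_D": self.defocus, "vs": self.values}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "TFVSCurve":
        df = pd.read_csv(path)
        if not {"defocus_D", "vs"}.issubset(df.columns):
            raise ValueError("TFVS CSV must have columns defocus_D,vs")
        df = df.sort_values("defocus_D")
        return cls(df["defocus_D"].to_numpy(), df["vs"].to_numpy(), **kwargs)


@dataclass
class DFVACurve:
    """Defocus visual-acuity curve: logMAR acuity per vergence (diopters).

    Stored sorted by decreasing vergence (+1.00 D first, −4.00 D last),
    the order in which clinical defocus curves are tabulated.
    """

    vergence: np.ndarray
    logmar: np.ndarray
    label: str = ""
    subject_id: str | None = None

    def __post_init__(self) -> None:
        v = _as_float_array(self.vergence)
        y = _as_float_array(self.logmar)
        if v.size != y.size:
            raise ValueError("vergence and logmar must have equal length")
        if np.unique(v).size != v.size:
            raise ValueError("duplicate vergence points")
        if not np.all(np.isfinite(y)):
            raise ValueError("logMAR values must be finite")
        order = np.argsort(-v)
        self.vergence = v[order]
        self.logmar = y[order]

    def value_at(self, vergence: float, atol: float = 1e-6) -> float:
        """Exact-grid lookup; raises if the vergence is not measured."""
        i = np.flatnonzero(np.abs(self.vergence - vergence) <= atol)
        if i.size == 0:
            raise KeyError(f"no measurement at {vergence:+.2f} D for '{self.label}'")
        return float(self.logmar[i[0]])

    def shifted(self, offset: float) -> "DFVACurve":
        """Additive logMAR offset; shape is unchanged."""
        return DFVACurve(self.vergence.copy(), self.logmar + offset,
                         label=self.label, subject_id=self.subject_id)


@dataclass
class AgreementReport:
    """Agreement metrics between two curves on a common grid."""

    cross_correlation: float
    rmse: float
    peak_shift: float

    def to_dict(self) -> dict[str, float]:
        return {
            "cross_correlation": self.cross_correlation,
            "rmse": self.rmse,
            "peak_shift_D": self.peak_shift,
        }


def _curve_xy(curve) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(curve, DFVACurve):
        # ascending axis for interpolation / peak finding
        return curve.vergence[::-1], curve.logmar[::-1]
    return curve.defocus, curve.values


def _peak_locations(x: np.ndarray, y: np.ndarray,
                    height_frac: float = 0.2,
                    prominence_frac: float = 0.05) -> np.ndarray:
    """Local maxima above ``height_frac`` of the max, with a minimum
    prominence; falls back to the global maximum for peak-free curves."""
    ymax = float(np.max(y))
    if ymax <= 0:
        return x[[int(np.argmax(y))]]
    idx, _ = find_peaks(y, height=height_frac * ymax, prominence=prominence_frac * ymax)
    if idx.size == 0:
        return x[[int(np.argmax(y))]]
    return x[idx]


def compare_curves(a, b, *, peak_height_frac: float = 0.2,
                   peak_prominence_frac: float = 0.05) -> AgreementReport:
    """Agreement between two curves of the same type.

    ``b`` is linearly resampled onto ``a``'s grid restricted to the common
    support.  Returns the zero-lag Pearson correlation, the pointwise RMSE
    and the largest defocus distance between matched local maxima (each
    peak of either curve is paired greedily with the nearest peak of the
    other, so spurious or missing peaks are penalised).
    """
    xa, ya = _curve_xy(a)
    xb, yb = _curve_xy(b)
    lo, hi = max(xa[0], xb[0]), min(xa[-1], xb[-1])
    m = (xa >= lo - 1e-9) & (xa <= hi + 1e-9)
    x = xa[m]
    if x.size < 3:
        raise ValueError("fewer than 3 common grid points")
    va = ya[m]
    vb = np.interp(x, xb, yb)
    if np.std(va) == 0 or np.std(vb) == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(np.corrcoef(va, vb)[0, 1])
    rmse = float(np.sqrt(np.mean((va - vb) ** 2)))
    pa = _peak_locations(x, va, peak_height_frac, peak_prominence_frac)
    pb = _peak_locations(x, vb, peak_height_frac, peak_prominence_frac)
    shift = max(
        max(float(np.min(np.abs(pb - p))) for p in pa),
        max(float(np.min(np.abs(pa - p))) for p in pb),
    )
    return AgreementReport(cross_correlation=r, rmse=rmse, peak_shift=shift)
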
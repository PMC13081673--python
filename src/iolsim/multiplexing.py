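"""Temporal multiplexing: programming a tunable lens to mimic a target
through-focus visual Strehl curve.

A multiplexed simulation cycles the optical power of a tunable lens
through a small set of additions within one 20 ms cycle (50 Hz).  The
fraction of the cycle spent at each addition — the temporal coefficient —
weights that addition's monofocal through-focus response, and the
dwell-weighted mixture reproduces the target TFVS.  Solving for the
coefficients is a sparse nonnegative least-squares problem over a 0.05 D
addition grid.

The central object is :class:`TemporalMultiplexModel`, a statsmodels-style
model whose :meth:`~TemporalMultiplexModel.fit` returns a
:class:`TemporalMultiplexResults` carrying the solved profile, the fitted
curve and agreement diagnostics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.optimize import nnls

from .curves import AgreementReport, TFVSCurve, compare_curves
from .optics import MonofocalKernel

__all__ = [
    "TemporalProfile",
    "TemporalMultiplexModel",
    "TemporalMultiplexResults",
    "solve_temporal_coefficients",
    "reconstruct_tfvs",
    "simulate_lens_power",
    "effective_profile",
    "simulate_focimeter",
    "compensate_profile",
]

DEFAULT_ADDITION_STEP = 0.05  # diopters
DEFAULT_ADDITION_RANGE = (-0.5, 4.5)  # diopters of add


def default_addition_grid(lo: float = DEFAULT_ADDITION_RANGE[0],
                          hi: float = DEFAULT_ADDITION_RANGE[1],
                          step: float = DEFAULT_ADDITION_STEP) -> np.ndarray:
    return np.round(np.arange(lo, hi + 1e-9, step), 10)


@dataclass
class TemporalProfile:
    """One 20 ms multiplexing cycle: additions and their dwell fractions.

    An addition ``a`` (diopters of extra power for near) places its
    monofocal response at defocus ``-a`` on the vergence axis.
    """

    additions: np.ndarray
    dwell_fractions: np.ndarray
    cycle_ms: float = 20.0
    rate_hz: float = 50.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        a = np.asarray(self.additions, dtype=float)
        f = np.asarray(self.dwell_fractions, dtype=float)
        if a.size != f.size or a.size == 0:
            raise ValueError("additions and dwell fractions must match and be non-empty")
        if np.unique(a).size != a.size:
            raise ValueError("additions must be unique")
        if np.any(f <= 0) or np.any(f > 1):
            raise ValueError("dwell fractions must lie in (0, 1]")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("dwell fractions must sum to 1")
        order = np.argsort(a)
        self.additions = a[order]
        self.dwell_fractions = f[order]

    @property
    def n_states(self) -> int:
        return int(self.additions.size)

    @property
    def dwell_times_ms(self) -> np.ndarray:
        return self.dwell_fractions * self.cycle_ms

    @property
    def amplitude(self) -> float:
        """Overall scale of the fitted mixture (1.0 if never fitted)."""
        return float(self.meta.get("amplitude", 1.0))

    def to_dict(self) -> dict[str, Any]:
        return {
            "cycle_ms": self.cycle_ms,
            "rate_hz": self.rate_hz,
            "states": [
                {"addition_D": float(a), "dwell_fraction": float(f)}
                for a, f in zip(self.additions, self.dwell_fractions)
            ],
            "meta": {k: v for k, v in self.meta.items()
                     if isinstance(v, (int, float, str, bool))},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "TemporalProfile":
        states = d["states"]
        return cls(
            additions=np.array([s["addition_D"] for s in states]),
            dwell_fractions=np.array([s["dwell_fraction"] for s in states]),
            cycle_ms=d.get("cycle_ms", 20.0),
            rate_hz=d.get("rate_hz", 50.0),
            meta=dict(d.get("meta", {})),
        )

    @classmethod
    def from_json(cls, path) -> "TemporalProfile":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _design_matrix(grid: np.ndarray, additions: np.ndarray,
                   kernel: MonofocalKernel) -> np.ndarray:
    return np.stack([kernel(grid + a) for a in additions], axis=1)


class TemporalMultiplexModel:
    """Sparse nonnegative mixture model for temporal coefficients.

    Fits ``target(d) ≈ Σ_k c_k · kernel(d + a_k)`` over a candidate
    addition grid by nonnegative least squares, then prunes to a sparse
    dwell profile by backward elimination: at each step the active
    coefficient whose removal raises the residual RMSE least is dropped
    and the remainder refitted.  Coefficients below ``prune_fraction`` of
    the cycle are always dropped; elimination continues beyond that while
    each step costs at most ``rmse_step_tol`` RMSE.

    Parameters
    ----------
    target : TFVSCurve
        The estimated TFVS the multiplexed lens must reproduce.
    kernel : MonofocalKernel
        Through-focus response of a single focal state.  Use a kernel
        passed through the estimation filter (:func:`iolsim.tfvs.smooth_kernel`)
        when the target is a filtered estimate.
    addition_grid : array of diopters, optional
        Candidate additions (default −0.50 to +4.50 D in 0.05 D steps).
    """

    def __init__(self, target: TFVSCurve, kernel: MonofocalKernel,
                 addition_grid: np.ndarray | None = None,
                 prune_fraction: float = 0.01,
                 rmse_step_tol: float = 0.001) -> None:
        if not np.any(target.values > 0):
            raise ValueError("target curve is identically zero")
        if not (0 <= prune_fraction < 1):
            raise ValueError("prune_fraction must lie in [0, 1)")
        self.target = target
        self.kernel = kernel
        self.addition_grid = (default_addition_grid() if addition_grid is None
                              else np.asarray(addition_grid, dtype=float))
        self.prune_fraction = prune_fraction
        self.rmse_step_tol = rmse_step_tol
        span = float(target.defocus[-1] - target.defocus[0])
        half = kernel.values >= 0.5
        fwhm = float(kernel.offsets[half][-1] - kernel.offsets[half][0])
        if fwhm > span:
            warnings.warn("kernel is wider (FWHM) than the target support: "
                          "the mixture problem may be ill-posed", stacklevel=2)
        self._design = _design_matrix(target.defocus, self.addition_grid, kernel)

    def _rmse(self, coef: np.ndarray) -> float:
        return float(np.sqrt(np.mean((self.target.values - self._design @ coef) ** 2)))

    def fit(self, prune: bool = True) -> "TemporalMultiplexResults":
        """Solve the nonnegative mixture; ``prune=False`` skips the
        backward elimination and returns the raw NNLS solution."""
        y = self.target.values
        coef, _ = nnls(self._design, y)
        if not np.any(coef > 0):
            raise ValueError("nonnegative fit is identically zero")
        rmse = self._rmse(coef)
        n_prunes = 0
        max_step_cost = 0.0
        while prune and np.count_nonzero(coef > 0) > 1:
            active = np.flatnonzero(coef > 0)
            frac = coef / coef.sum()
            mandatory = frac[active] < self.prune_fraction
            candidates = active[mandatory] if mandatory.any() else active
            best: tuple[float, np.ndarray] | None = None
            for j in candidates:
                keep = coef > 0
                keep[j] = False
                sub, _ = nnls(self._design[:, keep], y)
                trial = np.zeros_like(coef)
                trial[keep] = sub
                trial_rmse = self._rmse(trial)
                if best is None or trial_rmse < best[0]:
                    best = (trial_rmse, trial)
            assert best is not None
            if not mandatory.any() and best[0] - rmse > self.rmse_step_tol:
                break
            max_step_cost = max(max_step_cost, best[0] - rmse)
            rmse, coef = best[0], best[1]
            n_prunes += 1
        return TemporalMultiplexResults(self, coef, n_prunes, max_step_cost)


class TemporalMultiplexResults:
    """Fit results: the temporal profile, fitted curve and diagnostics."""

    def __init__(self, model: TemporalMultiplexModel, coefficients: np.ndarray,
                 n_prunes: int, max_prune_cost: float) -> None:
        self.model = model
        self.coefficients = coefficients
        self.n_prunes = n_prunes
        self.max_prune_cost = max_prune_cost
        active = coefficients > 0
        amp = float(coefficients[active].sum())
        self.profile = TemporalProfile(
            additions=model.addition_grid[active],
            dwell_fractions=coefficients[active] / amp,
            meta={"amplitude": amp, "rmse": self.rmse,
                  "n_states": int(active.sum())},
        )

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.model._design @ self.coefficients

    @property
    def fitted_curve(self) -> TFVSCurve:
        t = self.model.target
        return TFVSCurve(t.defocus, self.fittedvalues, plane=t.plane,
                         meta={"kind": "reconstructed"})

    @property
    def resid(self) -> np.ndarray:
        return self.model.target.values - self.fittedvalues

    @property
    def rmse(self) -> float:
        return float(np.sqrt(np.mean(self.resid ** 2)))

    @property
    def n_states(self) -> int:
        return self.profile.n_states

    def agreement(self) -> AgreementReport:
        """Agreement between the target and the fitted (reconstructed) TFVS."""
        return compare_curves(self.model.target, self.fitted_curve)

    def summary(self) -> str:
        rep = self.agreement()
        lines = [
            "Temporal multiplexing fit",
            "=" * 48,
            f"{'n target samples':<28}{self.model.target.defocus.size:>20}",
            f"{'n candidate additions':<28}{self.model.addition_grid.size:>20}",
            f"{'n states (coefficients)':<28}{self.n_states:>20}",
            f"{'backward-elimination steps':<28}{self.n_prunes:>20}",
            f"{'residual RMSE (VS units)':<28}{self.rmse:>20.5f}",
            f"{'cross-correlation':<28}{rep.cross_correlation:>20.5f}",
            f"{'mixture amplitude':<28}{self.profile.amplitude:>20.5f}",
            "-" * 48,
            f"{'addition (D)':>14}{'dwell fraction':>18}{'dwell (ms)':>14}",
        ]
        for a, f, t in zip(self.profile.additions, self.profile.dwell_fractions,
                           self.profile.dwell_times_ms):
            lines.append(f"{a:>14.2f}{f:>18.4f}{t:>14.2f}")
        return "\n".join(lines)


def solve_temporal_coefficients(target: TFVSCurve, kernel: MonofocalKernel,
                                addition_grid: np.ndarray | None = None,
                                prune_fraction: float = 0.01,
                                rmse_step_tol: float = 0.001) -> TemporalProfile:
    """Functional wrapper around :class:`TemporalMultiplexModel`."""
    return TemporalMultiplexModel(target, kernel, addition_grid,
                                  prune_fraction, rmse_step_tol).fit().profile


def reconstruct_tfvs(profile: TemporalProfile, kernel: MonofocalKernel,
                     grid: np.ndarray, scale: float | None = None,
                     plane: str = "IOL") -> TFVSCurve:
    """Dwell-weighted sum of shifted kernels on ``grid``.

    ``scale`` defaults to the profile's fitted mixture amplitude so that a
    profile solved from an estimated TFVS reconstructs on that curve's
    scale; pass ``scale=1`` for a unit-sum reconstruction.
    """
    grid = np.asarray(grid, dtype=float)
    if scale is None:
        scale = profile.amplitude
    vals = np.zeros_like(grid)
    for a, f in zip(profile.additions, profile.dwell_fractions):
        vals += f * kernel(grid + a)
    return TFVSCurve(grid, scale * vals, plane=plane,
                     meta={"kind": "reconstructed"})


def _state_order(profile: TemporalProfile, order: str) -> np.ndarray:
    if order == "ascending":
        return np.argsort(profile.additions)
    if order == "descending":
        return np.argsort(-profile.additions)
    raise ValueError("order must be 'ascending' or 'descending'")


def simulate_lens_power(profile: TemporalProfile, time_constant_ms: float = 1.0,
                        sample_rate_khz: float = 100.0, n_cycles: int = 4,
                        order: str = "ascending"
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """First-order-lag response of the tunable lens over ``n_cycles``.

    Returns ``(t_ms, commanded_D, actual_D)``.  The commanded power is a
    periodic staircase of the profile's additions (ascending by default);
    the lens follows with an exponential lag of the given time constant.
    """
    if time_constant_ms < 0:
        raise ValueError("time constant must be >= 0")
    dt = 1.0 / sample_rate_khz  # ms
    min_dwell = float(np.min(profile.dwell_times_ms))
    if dt > min_dwell:
        raise ValueError(
            f"sample interval {dt:g} ms exceeds the shortest dwell "
            f"{min_dwell:g} ms: undersampled")
    idx = _state_order(profile, order)
    adds = profile.additions[idx]
    fracs = profile.dwell_fractions[idx]
    edges = np.concatenate([[0.0], np.cumsum(fracs) * profile.cycle_ms])
    n = int(round(n_cycles * profile.cycle_ms / dt))
    t = (np.arange(n) + 0.5) * dt
    tc = t % profile.cycle_ms
    state = np.clip(np.searchsorted(edges, tc, side="right") - 1, 0, adds.size - 1)
    cmd = adds[state]
    actual = np.empty(n)
    p = cmd[0]
    alpha = np.exp(-dt / time_constant_ms) if time_constant_ms > 0 else 0.0
    for i in range(n):
        p = cmd[i] + (p - cmd[i]) * alpha
        actual[i] = p
    return t, cmd, actual


def effective_profile(profile: TemporalProfile, time_constant_ms: float = 1.0,
                      sample_rate_khz: float = 100.0,
                      bin_step: float = DEFAULT_ADDITION_STEP,
                      n_cycles: int = 4, order: str = "ascending"
                      ) -> TemporalProfile:
    """Dwell profile the lens actually realises under first-order dynamics.

    The instantaneous power over the last simulated cycle is binned onto
    the addition grid; bin occupancies become the effective dwell
    fractions (the quantity a high-speed focimeter measures).
    """
    t, _, actual = simulate_lens_power(profile, time_constant_ms,
                                       sample_rate_khz, n_cycles, order)
    per_cycle = int(round(profile.cycle_ms * sample_rate_khz))
    last = actual[-per_cycle:]
    bins = np.round(last / bin_step).astype(int)
    uniq, counts = np.unique(bins, return_counts=True)
    return TemporalProfile(
        additions=uniq * bin_step,
        dwell_fractions=counts / counts.sum(),
        cycle_ms=profile.cycle_ms, rate_hz=profile.rate_hz,
        meta=dict(profile.meta, time_constant_ms=time_constant_ms,
                  kind="effective"),
    )


def simulate_focimeter(profile: TemporalProfile, kernel: MonofocalKernel,
                       grid: np.ndarray, time_constant_ms: float = 1.0,
                       sample_rate_khz: float = 100.0,
                       order: str = "ascending") -> TFVSCurve:
    """Experimental TFVS under simulated high-speed focimetry.

    Simulates the lens response to the commanded profile, converts the
    measured power trace into effective dwell fractions and reconstructs
    the TFVS from them.  With ``time_constant_ms=0`` this equals
    :func:`reconstruct_tfvs` exactly.
    """
    eff = effective_profile(profile, time_constant_ms, sample_rate_khz,
                            order=order)
    return reconstruct_tfvs(eff, kernel, grid, scale=profile.amplitude)


def compensate_profile(profile: TemporalProfile, time_constant_ms: float = 1.0,
                       sample_rate_khz: float = 100.0, n_iter: int = 8,
                       order: str = "ascending",
                       kernel: MonofocalKernel | None = None,
                       grid: np.ndarray | None = None) -> TemporalProfile:
    """Iteratively adjust commanded dwells to counter the lens lag.

    The tunable lens spends part of each dwell slewing, so the effective
    dwell at each commanded state falls short of the nominal fraction.
    This fixed-point loop measures the shortfall with the simulated
    focimeter and rescales the commanded fractions until the effective
    profile best matches the nominal one — the simulation-side analogue of
    tuning the hardware drive signal against focimeter feedback.

    When ``kernel``/``grid`` are given the iterate minimizing the
    reconstruction RMSE against the nominal reconstruction is returned;
    otherwise the dwell-fraction mismatch is minimized.
    """
    nominal = profile.dwell_fractions
    cmd = nominal.copy()
    # commanded dwells must stay resolvable by the power-trace sampling
    floor = 2.0 / (sample_rate_khz * profile.cycle_ms)
    best: tuple[float, np.ndarray] | None = None
    recon_nom = (reconstruct_tfvs(profile, kernel, grid)
                 if kernel is not None and grid is not None else None)
    for _ in range(n_iter):
        f_cmd = np.maximum(cmd / cmd.sum(), floor)
        f_cmd = f_cmd / f_cmd.sum()
        trial = TemporalProfile(profile.additions, f_cmd,
                                profile.cycle_ms, profile.rate_hz,
                                meta=dict(profile.meta))
        eff = effective_profile(trial, time_constant_ms, sample_rate_khz,
                                order=order)
        eff_at_state = np.array([
            float(eff.dwell_fractions[np.abs(eff.additions - a) < 0.026].sum())
            for a in profile.additions])
        if recon_nom is not None:
            recon_eff = reconstruct_tfvs(eff, kernel, grid,
                                         scale=profile.amplitude)
            cost = float(np.sqrt(np.mean((recon_nom.values - recon_eff.values) ** 2)))
        else:
            cost = float(np.max(np.abs(eff_at_state - nominal)))
        if best is None or cost < best[0]:
            best = (cost, f_cmd)
        ratio = np.where(eff_at_state > 1e-6,
                         nominal / np.maximum(eff_at_state, 1e-6), 1.0)
        cmd = np.maximum(cmd * ratio, floor)
    assert best is not None
    return TemporalProfile(profile.additions, best[1], profile.cycle_ms,
                           profile.rate_hz,
                           meta=dict(profile.meta, compensated=True,
                                     time_constant_ms=time_constant_ms))
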
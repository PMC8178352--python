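"""Distances between a stepwise target IICR and a candidate model IICR.

Two objectives drive the curve fit.  The weighted distance integrates the
absolute difference between the curves against a weight proportional to
``f0^omega``, where ``f0`` is the coalescence-time density implied by the
target itself: regions where many coalescences happened (and where an
estimated curve is most trustworthy) count more, and the weight-shifting
exponent ``omega`` dampens (< 1) or exaggerates (> 1) that emphasis.  The
visual distance is the plain sum of node differences — what the eye sees
on a log-time plot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .iicr import StepwiseIICR, demography_iicr

__all__ = [
    "DistanceSpec",
    "reconstruct_density",
    "compute_weights",
    "distance_omega",
    "distance_visual",
    "curve_distance",
]


@dataclass(frozen=True)
class DistanceSpec:
    """Which distance to use and how.

    ``kind`` is ``"omega"`` (density-weighted) or ``"visual"``;
    ``omega > 0`` is the weight-shifting exponent; ``time_range``, when
    set, restricts the sum to grid intervals whose right endpoint lies in
    ``[g_min, g_max]`` (same units as the target grid).
    """

    kind: str = "omega"
    omega: float = 1.0
    time_range: tuple = None

    def __post_init__(self):
        if self.kind not in ("omega", "visual"):
            raise ValueError(f"unknown distance kind {self.kind!r}")
        if not self.omega > 0:
            raise ValueError("omega must be positive")
        if self.time_range is not None:
            lo, hi = self.time_range
            if not lo < hi:
                raise ValueError("time_range must satisfy g_min < g_max")
            object.__setattr__(self, "time_range", (float(lo), float(hi)))


def reconstruct_density(target: StepwiseIICR) -> np.ndarray:
    """Coalescence-time density ``f0`` implied by the target, at its grid nodes.

    The survival function of a stepwise IICR is
    ``S(tau_j) = exp(sum_k (tau_{k-1} - tau_k) / y_k)`` and the density is
    ``S(t) / IICR(t)``.  The step function is right-continuous, so the node
    ``tau_j`` divides by the value on the interval starting there; the last
    node (outside every interval) falls back to the final value.
    """
    tau = target.grid
    y = target.values
    if np.any(y <= 0):
        raise ValueError("IICR values must be positive")
    log_surv = np.concatenate([[0.0], np.cumsum(np.diff(tau) * (-1.0 / y))])
    divisors = np.concatenate([y, [y[-1]]])
    return np.exp(log_surv) / divisors


def compute_weights(f0: np.ndarray, omega: float) -> np.ndarray:
    """Normalize ``f0 ** omega`` to sum to one (plain sum, no interval widths)."""
    f0 = np.asarray(f0, dtype=float)
    if not omega > 0:
        raise ValueError("omega must be positive")
    if np.all(f0 == 0):
        raise ValueError("density is identically zero")
    powered = f0**omega
    return powered / powered.sum()


def _candidate_values(candidate, times: np.ndarray) -> np.ndarray:
    """Evaluate a candidate IICR at grid nodes.

    Accepts a demography (exact IICR, scaled if applicable), a stepwise
    curve, or any callable of time.
    """
    from .demography import IslandDemography, ScaledDemography

    if isinstance(candidate, (IslandDemography, ScaledDemography)):
        grid = np.concatenate([[0.0], times])
        return demography_iicr(candidate, grid).values
    if isinstance(candidate, StepwiseIICR):
        # left limit at the nodes, so a curve is at zero distance to itself
        idx = np.clip(
            np.searchsorted(candidate.grid, times, side="left") - 1,
            0,
            len(candidate.values) - 1,
        )
        return candidate.values[idx]
    if callable(candidate):
        return np.asarray(candidate(times), dtype=float)
    raise TypeError(f"cannot evaluate candidate of type {type(candidate).__name__}")


def _kept_intervals(target: StepwiseIICR, spec: DistanceSpec) -> np.ndarray:
    left, right = target.grid[:-1], target.grid[1:]
    if spec.time_range is None:
        return np.ones(len(right), dtype=bool)
    lo, hi = spec.time_range
    keep = (left >= lo) & (right <= hi)
    if not keep.any():
        raise ValueError("time_range excludes every grid interval")
    return keep


def distance_omega(target: StepwiseIICR, candidate, spec: DistanceSpec = None) -> float:
    """Density-weighted L1 distance between target and candidate.

    ``sum_j |y_j - IICR_phi(tau_j)| w(tau_{j-1}) (tau_j - tau_{j-1})`` with
    weights from the target's reconstructed density at the left endpoints,
    renormalized over the intervals kept by ``spec.time_range``.
    """
    spec = spec or DistanceSpec()
    keep = _kept_intervals(target, spec)
    f0_left = reconstruct_density(target)[:-1]
    w = compute_weights(f0_left[keep], spec.omega)
    widths = np.diff(target.grid)[keep]
    y = target.values[keep]
    cand = _candidate_values(candidate, target.grid[1:])[keep]
    return float(np.sum(np.abs(y - cand) * w * widths))


def distance_visual(target: StepwiseIICR, candidate, spec: DistanceSpec = None) -> float:
    """Plain sum of absolute node differences (assumes a log-spaced grid)."""
    spec = spec or DistanceSpec(kind="visual")
    keep = _kept_intervals(target, spec)
    y = target.values[keep]
    cand = _candidate_values(candidate, target.grid[1:])[keep]
    return float(np.sum(np.abs(y - cand)))


def curve_distance(target: StepwiseIICR, candidate, spec: DistanceSpec = None) -> float:
    """Dispatch on ``spec.kind``."""
    spec = spec or DistanceSpec()
    if spec.kind == "visual":
        return distance_visual(target, candidate, spec)
    return distance_omega(target, candidate, spec)
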
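"""Ion-stability metrics and the stable/unstable classifier.

Two statistics summarise how firmly the three Na+ ions sit in the
binding pocket over the tail of a trajectory:

* **RMSF** — per ion, the root of the time-averaged squared deviation of
  its position from its own window-average position,
  ``RMSF_i = sqrt(<|r_i(t) - <r_i>|^2>_t``.  No superposition is applied:
  each ion fluctuates about its own mean.
* **N_water** — the mean number of *unique* water molecules whose oxygen
  lies within a cutoff (default 5 Å) of any of the three ions; a water
  close to two ions at once still counts once.

A protonation state is called *stable* when every replica satisfies
``N_water < 8`` and ``RMSF < 0.5 Å`` (strict inequalities) and no ion
unbinds; any unbinding event excludes the state instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .trajectory import (InsufficientDataError, MetricWindow, Trajectory,
                         TrajectoryError, default_window)

__all__ = [
    "ReplicaMetrics",
    "StabilityThresholds",
    "StabilityReport",
    "ion_rmsf",
    "hydration_count",
    "detect_unbinding",
    "replica_metrics",
    "classify_stability",
]

logger = logging.getLogger(__name__)

STABLE = "stable"
UNSTABLE = "unstable"
EXCLUDED_UNBINDING = "excluded_unbinding"


@dataclass(frozen=True)
class StabilityThresholds:
    """Stability box: N_water < nwater and RMSF < rmsf (both strict)."""

    nwater: float = 8.0
    rmsf: float = 0.5  # Å
    escape: float = 5.0  # Å, unbinding displacement

    def __post_init__(self) -> None:
        if min(self.nwater, self.rmsf, self.escape) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class ReplicaMetrics:
    """Per-replica summary used by the classifier."""

    per_ion_rmsf: np.ndarray  # (3,) Å
    mean_rmsf: float
    per_frame_nwater: np.ndarray  # ints over the window
    mean_nwater: float
    unbound: np.ndarray  # (3,) bool

    @property
    def any_unbound(self) -> bool:
        return bool(np.any(self.unbound))


@dataclass
class StabilityReport:
    """Stability verdict for one protonation state across replicas."""

    symbol: str
    replicas: list[ReplicaMetrics]
    verdict: str
    thresholds: StabilityThresholds
    failures: list[str] = field(default_factory=list)


def _window_mask(traj: Trajectory, window: Optional[MetricWindow]) -> np.ndarray:
    if window is None:
        window = default_window(traj)
    return window.frame_mask(traj)


def ion_rmsf(traj: Trajectory, window: Optional[MetricWindow] = None
             ) -> tuple[np.ndarray, float]:
    """Per-ion RMSF over the window plus the mean over ions (Å).

    Raises :class:`InsufficientDataError` when fewer than two sampled
    frames fall inside the window.
    """
    mask = _window_mask(traj, window)
    if mask.sum() < 2:
        raise InsufficientDataError(
            f"RMSF needs >= 2 frames in the window; got {int(mask.sum())}")
    pos = traj.ion_coords()[mask]  # (F, n_ion, 3)
    mean_pos = pos.mean(axis=0, keepdims=True)
    sq = ((pos - mean_pos) ** 2).sum(axis=2)  # (F, n_ion)
    per_ion = np.sqrt(sq.mean(axis=0))
    return per_ion, float(per_ion.mean())


def _pairwise_dist2(a: np.ndarray, b: np.ndarray,
                    box: Optional[np.ndarray]) -> np.ndarray:
    """Squared distances between frame-stacked point sets.

    a: (F, n, 3), b: (F, m, 3) -> (F, n, m).  Orthorhombic minimum-image
    convention applied when a box is given.
    """
    d = a[:, :, None, :] - b[:, None, :, :]
    if box is not None:
        d -= box * np.round(d / box)
    return (d ** 2).sum(axis=-1)


def hydration_count(traj: Trajectory, cutoff: float = 5.0,
                    window: Optional[MetricWindow] = None
                    ) -> tuple[np.ndarray, float]:
    """Per-frame unique-water counts within *cutoff* of any ion, plus mean.

    A water molecule counts once per frame if its oxygen lies within
    *cutoff* of ANY ion.  With no waters present the count is zero and a
    warning is logged.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    mask = _window_mask(traj, window)
    if traj.water_indices.size == 0:
        logger.warning("hydration_count: trajectory has no water particles")
        return np.zeros(int(mask.sum()), dtype=int), 0.0
    ions = traj.ion_coords()[mask]
    waters = traj.water_coords()[mask]
    d2 = _pairwise_dist2(waters, ions, traj.box)  # (F, n_water, n_ion)
    near_any = (d2 <= cutoff ** 2).any(axis=2)
    counts = near_any.sum(axis=1).astype(int)
    return counts, float(counts.mean())


def detect_unbinding(traj: Trajectory,
                     site_centers: Optional[np.ndarray] = None,
                     escape_threshold: float = 5.0,
                     window: Optional[MetricWindow] = None) -> np.ndarray:
    """Flag ions whose final-frame displacement exceeds the escape threshold.

    Reference points default to each ion's first-frame position.  Only the
    final frame of the window is inspected: an excursion that returns
    inside the threshold is not an unbinding event.
    """
    mask = _window_mask(traj, window)
    ions = traj.ion_coords()
    refs = (ions[0] if site_centers is None
            else np.asarray(site_centers, dtype=float))
    if refs.shape != ions[0].shape:
        raise TrajectoryError("need one reference point per ion")
    final = ions[np.flatnonzero(mask)[-1]]
    d = final - refs
    if traj.box is not None:
        d -= traj.box * np.round(d / traj.box)
    return np.linalg.norm(d, axis=1) > escape_threshold


def replica_metrics(traj: Trajectory, cutoff: float = 5.0,
                    window: Optional[MetricWindow] = None,
                    escape_threshold: float = 5.0,
                    site_centers: Optional[np.ndarray] = None) -> ReplicaMetrics:
    """Compute all per-replica quantities the classifier needs."""
    per_ion, mean_rmsf = ion_rmsf(traj, window)
    counts, mean_nwater = hydration_count(traj, cutoff, window)
    unbound = detect_unbinding(traj, site_centers, escape_threshold, window)
    return ReplicaMetrics(per_ion_rmsf=per_ion, mean_rmsf=mean_rmsf,
                          per_frame_nwater=counts, mean_nwater=mean_nwater,
                          unbound=unbound)


def classify_stability(symbol: str, replicas: Sequence[ReplicaMetrics],
                       thresholds: StabilityThresholds = StabilityThresholds()
                       ) -> StabilityReport:
    """Stable iff every replica sits strictly inside the stability box.

    Any ion unbinding in any replica excludes the state
    (verdict ``excluded_unbinding``) before the box test is applied.
    """
    if not replicas:
        raise ValueError(f"state {symbol}: no replicas to classify")
    failures: list[str] = []
    verdict = STABLE
    if any(r.any_unbound for r in replicas):
        verdict = EXCLUDED_UNBINDING
        for i, r in enumerate(replicas):
            if r.any_unbound:
                ions = np.flatnonzero(r.unbound).tolist()
                failures.append(f"replica {i}: ion(s) {ions} unbound")
    else:
        for i, r in enumerate(replicas):
            if not r.mean_nwater < thresholds.nwater:
                failures.append(
                    f"replica {i}: N_water {r.mean_nwater:.2f} >= {thresholds.nwater}")
            if not r.mean_rmsf < thresholds.rmsf:
                failures.append(
                    f"replica {i}: RMSF {r.mean_rmsf:.3f} >= {thresholds.rmsf}")
        if failures:
            verdict = UNSTABLE
    return StabilityReport(symbol=symbol, replicas=list(replicas),
                           verdict=verdict, thresholds=thresholds,
                           failures=failures)
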
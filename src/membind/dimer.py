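"""Dimer geometry and atomistic-resolution analyses.

Covers the hinge-bending angle between the two kinase subunits (a
three-point angle whose default anchors are the catalytic-lysine and
interface-valine backbone particles rather than build-specific atom serial
numbers), per-subunit membrane distances, geometric hydrogen-bond counting
(donor-acceptor distance <= 0.35 nm and H-D-A angle <= 30 degrees, the
common GROMACS convention), centred moving averages, and per-residue Ca RMSF
after superposition onto the time-average structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binding import DistanceSeries, Metric, com_distance_series
from .core import DIMER_SUBUNIT_OFFSET, SelectionError, Trajectory, select
from .geometry import com, kabsch, min_image_displacement, unwrap

__all__ = [
    "AngleSeries",
    "HBondCriterion",
    "UndefinedAngleError",
    "DEFAULT_HINGE_ANCHORS",
    "hinge_angle_series",
    "subunit_distance_series",
    "count_hbonds",
    "moving_average",
    "rmsf",
]


class UndefinedAngleError(ValueError):
    """Coincident anchor points leave the hinge angle undefined."""


#: Default hinge anchor selections: catalytic lysine of subunit A (simulation
#: residue 182), the interface valine of subunit A (residue 29) as vertex,
#: and the catalytic lysine of subunit B (residue 505 = 182 + 323).  Backbone
#: particles (Ca in atomistic, BB bead in coarse-grained) anchor the angle.
DEFAULT_HINGE_ANCHORS = (
    f"subunit A and resid 182 and name CA BB",
    f"subunit A and resid 29 and name CA BB",
    f"subunit B and resid {182 + DIMER_SUBUNIT_OFFSET} and name CA BB",
)


@dataclass
class AngleSeries:
    """Per-frame three-point angle in degrees."""

    times: np.ndarray
    theta: np.ndarray  # degrees in [0, 180]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.times.shape != self.theta.shape:
            raise ValueError("times and theta must have equal length")
        if np.any((self.theta < -1e-9) | (self.theta > 180 + 1e-9)):
            raise ValueError("theta must lie in [0, 180] degrees")


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric hydrogen-bond criterion (inclusive cutoffs)."""

    max_da_distance: float = 0.35  # nm, donor-acceptor
    max_hda_angle: float = 30.0    # degrees, hydrogen-donor-acceptor

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0 or self.max_hda_angle <= 0:
            raise ValueError("criterion cutoffs must be positive")


def _resolve(topology, sel) -> np.ndarray:
    if isinstance(sel, str):
        return select(topology, sel)
    return np.asarray(sel, dtype=int)


def hinge_angle_series(traj: Trajectory,
                       sel_arm_a: str = DEFAULT_HINGE_ANCHORS[0],
                       sel_vertex: str = DEFAULT_HINGE_ANCHORS[1],
                       sel_arm_b: str = DEFAULT_HINGE_ANCHORS[2],
                       ) -> AngleSeries:
    """Planar angle at the vertex selection's COM between the two arm COMs."""
    top = traj.topology
    ids = [_resolve(top, s) for s in (sel_arm_a, sel_vertex, sel_arm_b)]
    for s, i in zip((sel_arm_a, sel_vertex, sel_arm_b), ids):
        if i.size == 0:
            raise SelectionError(f"empty anchor selection {s!r}")
    theta = np.empty(len(traj))
    for fi, frame in enumerate(traj.frames):
        points = [com(unwrap(frame.coordinates[i], frame.box), top.masses[i])
                  for i in ids]
        a, v, b = points
        u = min_image_displacement(v, a, frame.box)
        w = min_image_displacement(v, b, frame.box)
        nu, nw = np.linalg.norm(u), np.linalg.norm(w)
        if nu < 1e-9 or nw < 1e-9:
            raise UndefinedAngleError(
                f"coincident anchor points in frame {fi}")
        c = np.clip(np.dot(u, w) / (nu * nw), -1.0, 1.0)
        theta[fi] = np.degrees(np.arccos(c))
    return AngleSeries(times=traj.times, theta=theta)


def subunit_distance_series(traj: Trajectory, subunit_sel: str,
                            membrane_sel: str = "not species protein",
                            metric: Metric = "z_component") -> DistanceSeries:
    """Per-subunit (or per-residue) COM distance from the membrane COM."""
    return com_distance_series(traj, subunit_sel, membrane_sel, metric=metric)


def count_hbonds(traj: Trajectory, donor_set, hydrogen_map: dict[int, list[int]],
                 acceptor_set, criterion: HBondCriterion = HBondCriterion(),
                 ) -> np.ndarray:
    """Per-frame count of hydrogen-bonding (donor, hydrogen, acceptor) triples.

    A triple counts when the donor-acceptor minimum-image distance is at most
    the distance cutoff and the hydrogen-donor-acceptor angle is at most the
    angle cutoff.  Acceptors identical to the donor or to one of its
    hydrogens are excluded.  Every donor must have at least one mapped
    hydrogen.
    """
    top = traj.topology
    donors = _resolve(top, donor_set)
    acceptors = _resolve(top, acceptor_set)
    if donors.size == 0 or acceptors.size == 0:
        raise SelectionError("empty donor or acceptor selection")
    for d in donors:
        if not hydrogen_map.get(int(d)):
            raise ValueError(f"donor particle {d} has no mapped hydrogen")
    cos_max = np.cos(np.radians(criterion.max_hda_angle))
    counts = np.zeros(len(traj), dtype=int)
    for fi, frame in enumerate(traj.frames):
        box = frame.box
        X = frame.coordinates
        n = 0
        for d in donors:
            hs = hydrogen_map[int(d)]
            excluded = {int(d), *map(int, hs)}
            da = np.array([min_image_displacement(X[d], X[a], box)
                           for a in acceptors])
            dists = np.linalg.norm(da, axis=1)
            for ai, a in enumerate(acceptors):
                if int(a) in excluded or dists[ai] > criterion.max_da_distance:
                    continue
                u = da[ai] / dists[ai]
                for h in hs:
                    dh = min_image_displacement(X[d], X[h], box)
                    ndh = np.linalg.norm(dh)
                    if ndh < 1e-9:
                        continue
                    if np.dot(dh / ndh, u) >= cos_max - 1e-12:
                        n += 1
        counts[fi] = n
    return counts


def moving_average(values: np.ndarray, times: np.ndarray | None = None,
                   window: float = 10.0) -> np.ndarray:
    """Centred moving average over a time window (ns), shrinking at the
    edges; output length equals input length."""
    if window <= 0:
        raise ValueError("window must be positive")
    values = np.asarray(values, dtype=float)
    t = np.arange(len(values), dtype=float) if times is None \
        else np.asarray(times, dtype=float)
    half = window / 2.0
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right")
    csum = np.concatenate([[0.0], np.cumsum(values)])
    return (csum[hi] - csum[lo]) / (hi - lo)


def rmsf(traj: Trajectory, selection: str = "name CA BB",
         reference: str = "average", max_iter: int = 10,
         tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue RMSF (nm) of backbone particles after superposition.

    Frames are first aligned to frame 1, then iteratively superposed onto
    the time-average structure (the common convention; pass
    ``reference="first"`` to keep the frame-1 reference).  Returns
    ``(residue_indices, rmsf)``.
    """
    if len(traj) < 2:
        raise ValueError("need at least 2 frames for RMSF")
    top = traj.topology
    ids = _resolve(top, selection)
    names = top.names[ids]
    backbone = np.isin(names, ("CA", "BB"))
    if not backbone.any():
        raise SelectionError(
            "selection contains no Ca/backbone-designated particles")
    ids = ids[backbone]
    masses = top.masses[ids]
    coords = np.stack([unwrap(f.coordinates[ids], f.box)
                       for f in traj.frames])
    w = masses / masses.sum()

    def align_onto(X: np.ndarray, ref: np.ndarray) -> np.ndarray:
        R = kabsch(X, ref, masses)
        xc = X - (X * w[:, None]).sum(axis=0)
        rc = (ref * w[:, None]).sum(axis=0)
        return xc @ R.T + rc

    aligned = np.stack([align_onto(X, coords[0]) for X in coords])
    if reference == "average":
        for _ in range(max_iter):
            mean = aligned.mean(axis=0)
            new = np.stack([align_onto(X, mean) for X in aligned])
            shift = float(np.max(np.abs(new - aligned)))
            aligned = new
            if shift < tol:
                break
    mean = aligned.mean(axis=0)
    fluct = np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0))
    return top.residue_indices[ids], fluct
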
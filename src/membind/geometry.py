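"""Geometric primitives: centres of mass, periodic minimum-image distances,
Kabsch superposition, in-plane (xy) fitting and the Rzz orientation scalar.

Rzz is the (3,3) element of the least-squares rotation matrix between a frame
and a reference pose after removing in-plane translation and rotation about
the membrane normal (z): 1 means the same tilt as the reference, -1 an
inverted protein.  Boxes are orthorhombic throughout.
"""

from __future__ import annotations

import numpy as np

from .core import Frame, Topology

__all__ = [
    "DegenerateGeometryError",
    "center_of_mass",
    "com",
    "min_image_displacement",
    "min_image_distance",
    "unwrap",
    "kabsch",
    "fit_in_plane",
    "rzz",
]


class DegenerateGeometryError(ValueError):
    """Input geometry does not determine the requested quantity."""


def com(coordinates: np.ndarray, masses: np.ndarray | None = None) -> np.ndarray:
    """Mass-weighted mean position. Uniform weights if *masses* is None."""
    coordinates = np.asarray(coordinates, dtype=float)
    if coordinates.size == 0:
        raise ValueError("cannot compute centre of mass of an empty set")
    if masses is None:
        return coordinates.mean(axis=0)
    masses = np.asarray(masses, dtype=float)
    total = masses.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    return (coordinates * masses[:, None]).sum(axis=0) / total


def center_of_mass(topology: Topology, frame: Frame,
                   particle_ids: np.ndarray) -> np.ndarray:
    """Centre of mass of the selected particles (no PBC unwrapping here;
    callers unwrap molecules first where that matters)."""
    particle_ids = np.asarray(particle_ids, dtype=int)
    if particle_ids.size == 0:
        raise ValueError("empty particle selection")
    return com(frame.coordinates[particle_ids], topology.masses[particle_ids])


def min_image_displacement(p: np.ndarray, q: np.ndarray,
                           box: np.ndarray) -> np.ndarray:
    """Componentwise displacement q-p wrapped into (-L/2, L/2]."""
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box edges must be positive")
    delta = np.asarray(q, dtype=float) - np.asarray(p, dtype=float)
    return delta - box * np.round(delta / box)


def min_image_distance(p: np.ndarray, q: np.ndarray, box: np.ndarray) -> float:
    """Euclidean distance to the nearest periodic image."""
    return float(np.linalg.norm(min_image_displacement(p, q, box)))


def unwrap(coordinates: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Make a molecule whole by nearest-image chaining from its first particle.

    Every particle is placed at the image nearest to the first particle;
    adequate for compact molecules smaller than half the box.
    """
    coordinates = np.asarray(coordinates, dtype=float)
    delta = coordinates - coordinates[0]
    delta -= box * np.round(delta / np.asarray(box, dtype=float))
    return coordinates[0] + delta


def kabsch(X: np.ndarray, Y: np.ndarray,
           weights: np.ndarray | None = None) -> np.ndarray:
    """Proper rotation R minimising the weighted RMSD of R(X-COM_X) onto
    (Y-COM_Y).

    Reflections are corrected by the determinant sign of the SVD factors.
    Collinear (rank-deficient) inputs raise :class:`DegenerateGeometryError`.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("X and Y must be matching (N, 3) arrays")
    if X.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 points")
    if weights is None:
        w = np.ones(X.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    Xc = X - (X * w[:, None]).sum(axis=0)
    Yc = Y - (Y * w[:, None]).sum(axis=0)
    C = Xc.T @ (Yc * w[:, None])
    U, S, Vt = np.linalg.svd(C)
    if S[1] <= 1e-12 * max(S[0], 1e-300):
        raise DegenerateGeometryError(
            "points are collinear; rotation is underdetermined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def fit_in_plane(frame_coords: np.ndarray, reference_coords: np.ndarray,
                 weights: np.ndarray | None = None) -> np.ndarray:
    """Remove xy translation and rotation about z relative to the reference.

    The optimal z-rotation is the closed-form 2D least-squares angle; z
    coordinates (and hence tilt) are untouched apart from the rotation being
    purely about z.
    """
    F = np.asarray(frame_coords, dtype=float)
    R = np.asarray(reference_coords, dtype=float)
    if F.shape != R.shape:
        raise ValueError("frame and reference must have matching shapes")
    if weights is None:
        w = np.ones(F.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    f_com = (F * w[:, None]).sum(axis=0)
    r_com = (R * w[:, None]).sum(axis=0)
    Fc = F - f_com
    Rc = R - r_com
    num = np.sum(w * (Fc[:, 0] * Rc[:, 1] - Fc[:, 1] * Rc[:, 0]))
    den = np.sum(w * (Fc[:, 0] * Rc[:, 0] + Fc[:, 1] * Rc[:, 1]))
    if abs(num) < 1e-15 and abs(den) < 1e-15:
        raise DegenerateGeometryError(
            "degenerate xy projection: in-plane rotation undetermined")
    theta = np.arctan2(num, den)
    c, s = np.cos(theta), np.sin(theta)
    out = Fc.copy()
    out[:, 0] = c * Fc[:, 0] - s * Fc[:, 1]
    out[:, 1] = s * Fc[:, 0] + c * Fc[:, 1]
    # restore the reference xy COM; keep the frame's own z origin
    out[:, 0] += r_com[0]
    out[:, 1] += r_com[1]
    out[:, 2] += f_com[2]
    return out


def rzz(frame_coords: np.ndarray, reference_coords: np.ndarray,
        weights: np.ndarray | None = None) -> float:
    """Orientation scalar: the (3,3) rotation-matrix element between the
    in-plane-fitted frame and the reference pose."""
    aligned = fit_in_plane(frame_coords, reference_coords, weights)
    R = kabsch(aligned, reference_coords, weights)
    return float(np.clip(R[2, 2], -1.0, 1.0))
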
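"""Distance-orientation binding landscapes and mode detection.

The landscape is a 2D probability histogram over (|z| COM separation, Rzz)
pooled across replicate trajectories, relative to a "productively bound"
reference pose.  By default the reference frame is picked automatically as
the frame maximising contacts between the catalytic-site residues (the
DLKGS motif, simulation residues 180-184) and the substrate-lipid
headgroups.  Binding modes appear as local maxima of the (lightly smoothed)
landscape; the loop-first encounter pose and the productive
catalytic-site-down pose form two distinct peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, maximum_filter

from .binding import CG_CONTACT_CUTOFF, DistanceSeries, contact_timeseries
from .core import Trajectory, select
from .geometry import rzz, unwrap

__all__ = [
    "OrientationSeries",
    "DensityMap",
    "Mode",
    "DLKGS_RESIDUES",
    "pick_reference",
    "orientation_series",
    "distance_orientation_map",
    "find_modes",
]

#: Catalytic-site motif residues (simulation numbering).
DLKGS_RESIDUES = tuple(range(180, 185))


@dataclass
class OrientationSeries:
    """Per-frame Rzz orientation scalar against a named reference."""

    times: np.ndarray
    rzz: np.ndarray
    reference: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rzz = np.asarray(self.rzz, dtype=float)
        if self.times.shape != self.rzz.shape:
            raise ValueError("times and rzz must have equal length")
        if np.any(np.abs(self.rzz) > 1 + 1e-9):
            raise ValueError("|rzz| must be <= 1")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class DensityMap:
    """2D probability histogram over (distance, Rzz)."""

    d_edges: np.ndarray
    rzz_edges: np.ndarray
    probabilities: np.ndarray  # (n_bins_d, n_bins_r), sums to 1

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < 0):
            raise ValueError("probabilities must be >= 0")
        total = p.sum()
        if total > 0 and abs(total - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")
        self.probabilities = p

    @property
    def d_centers(self) -> np.ndarray:
        return 0.5 * (self.d_edges[:-1] + self.d_edges[1:])

    @property
    def rzz_centers(self) -> np.ndarray:
        return 0.5 * (self.rzz_edges[:-1] + self.rzz_edges[1:])


@dataclass
class Mode:
    """A local maximum of the landscape with its probability mass."""

    peak_distance: float
    peak_rzz: float
    mass: float
    label: str
    bin_index: tuple[int, int] = field(default=(0, 0))

    def __post_init__(self) -> None:
        if not 0 < self.mass <= 1 + 1e-12:
            raise ValueError("mode mass must lie in (0, 1]")


def pick_reference(trajs: Sequence[Trajectory],
                   catalytic_residues: Sequence[int] = DLKGS_RESIDUES,
                   lipid_target_sel: str = "species PI4P and headgroup",
                   cutoff: float = CG_CONTACT_CUTOFF,
                   protein_sel: str = "species protein",
                   reference_coords: np.ndarray | None = None,
                   ) -> tuple[np.ndarray, dict]:
    """Select the productively-bound reference pose.

    Default: across all trajectories, the frame in which the catalytic-site
    residues make the most contacts with the target-lipid headgroups; the
    returned coordinates are the (unwrapped) protein-selection coordinates of
    that frame.  A user-supplied ``reference_coords`` is passed through with
    provenance ``"user"``.
    """
    if reference_coords is not None:
        return np.asarray(reference_coords, float), {"source": "user"}
    if not trajs:
        raise ValueError("need at least one trajectory")
    best = (-1, None, None)  # (contacts, traj index, frame index)
    for ti, traj in enumerate(trajs):
        series = contact_timeseries(traj, protein_residues=catalytic_residues,
                                    lipid_target_sel=lipid_target_sel,
                                    cutoff=cutoff)
        per_frame = series.matrix.sum(axis=0)
        fi = int(np.argmax(per_frame))
        if per_frame[fi] > best[0]:
            best = (int(per_frame[fi]), ti, fi)
    n_contacts, ti, fi = best
    if n_contacts <= 0:
        raise ValueError(
            "no frame shows catalytic-site lipid contacts; supply a "
            "reference structure explicitly")
    traj = trajs[ti]
    ids = select(traj.topology, protein_sel)
    frame = traj.frames[fi]
    coords = unwrap(frame.coordinates[ids], frame.box)
    provenance = {"source": "max_catalytic_contacts", "trajectory": ti,
                  "frame": fi, "contacts": n_contacts}
    return coords, provenance


def orientation_series(traj: Trajectory, protein_sel: str,
                       reference: np.ndarray,
                       mass_weighted: bool = True) -> OrientationSeries:
    """Per-frame Rzz of the protein selection against the reference pose."""
    ids = select(traj.topology, protein_sel) if isinstance(protein_sel, str) \
        else np.asarray(protein_sel, int)
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (ids.size, 3):
        raise ValueError(
            f"reference has shape {reference.shape}, selection needs "
            f"({ids.size}, 3)")
    weights = traj.topology.masses[ids] if mass_weighted else None
    values = np.empty(len(traj))
    for i, frame in enumerate(traj.frames):
        coords = unwrap(frame.coordinates[ids], frame.box)
        values[i] = rzz(coords, reference, weights)
    return OrientationSeries(times=traj.times, rzz=values,
                             reference="supplied")


def distance_orientation_map(pairs: Sequence[tuple[DistanceSeries, OrientationSeries]],
                             n_bins_d: int = 50, n_bins_r: int = 50,
                             ranges: tuple[tuple[float, float],
                                           tuple[float, float]] | None = None,
                             ) -> DensityMap:
    """Pooled 2D probability histogram over replicate (distance, Rzz) frames.

    All replicate frames are pooled into one histogram (per-replicate
    averaging is statistically equivalent for equal-length replicates); bins
    span the observed ranges unless given explicitly.
    """
    if not pairs:
        raise ValueError("empty input")
    d_all, r_all = [], []
    for dist, orient in pairs:
        if len(dist) != len(orient) or not np.allclose(dist.times, orient.times):
            raise ValueError("distance and orientation series are not "
                             "time-aligned")
        d_all.append(dist.values)
        r_all.append(orient.rzz)
    d = np.concatenate(d_all)
    r = np.concatenate(r_all)
    if ranges is None:
        pad_d = max(np.ptp(d), 1e-6) * 1e-3
        pad_r = max(np.ptp(r), 1e-6) * 1e-3
        ranges = ((d.min() - pad_d, d.max() + pad_d),
                  (r.min() - pad_r, r.max() + pad_r))
    hist, d_edges, r_edges = np.histogram2d(
        d, r, bins=(n_bins_d, n_bins_r), range=ranges)
    total = hist.sum()
    if total == 0:
        raise ValueError("no frames fell inside the histogram ranges")
    return DensityMap(d_edges=d_edges, rzz_edges=r_edges,
                      probabilities=hist / total)


def find_modes(density_map: DensityMap, k: int = 2,
               smoothing: float = 1.0,
               min_separation: int = 2) -> list[Mode]:
    """Top-k local maxima of the Gaussian-smoothed landscape.

    Peaks are ranked by smoothed density and accepted greedily subject to a
    Chebyshev separation of at least *min_separation* bins; ties break toward
    the lowest distance bin, then the lowest Rzz bin.  Each accepted peak's
    mass is the probability assigned to it by nearest-peak partitioning of
    the bins.  If fewer maxima exist than requested, the available ones are
    returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    p = density_map.probabilities
    smooth = gaussian_filter(p, sigma=smoothing, mode="nearest") \
        if smoothing > 0 else p
    local_max = (smooth == maximum_filter(smooth, size=3, mode="nearest")) \
        & (smooth > 0)
    cand = np.argwhere(local_max)
    # rank: density desc, then low distance bin, then low rzz bin
    order = sorted(range(len(cand)),
                   key=lambda i: (-smooth[tuple(cand[i])], cand[i][0], cand[i][1]))
    peaks: list[tuple[int, int]] = []
    for i in order:
        ij = tuple(int(x) for x in cand[i])
        if all(max(abs(ij[0] - p0), abs(ij[1] - p1)) >= min_separation
               for p0, p1 in peaks):
            peaks.append(ij)
        if len(peaks) == k:
            break
    if len(peaks) < k:
        warnings.warn(f"only {len(peaks)} local maxima found (requested {k})")
    if not peaks:
        return []
    # nearest-peak assignment of probability mass
    ii, jj = np.meshgrid(np.arange(p.shape[0]), np.arange(p.shape[1]),
                         indexing="ij")
    dist2 = np.stack([(ii - pi) ** 2 + (jj - pj) ** 2 for pi, pj in peaks])
    nearest = np.argmin(dist2, axis=0)
    d_centers = density_map.d_centers
    r_centers = density_map.rzz_centers
    modes = []
    for m, (pi, pj) in enumerate(peaks):
        mass = float(p[nearest == m].sum())
        modes.append(Mode(peak_distance=float(d_centers[pi]),
                          peak_rzz=float(r_centers[pj]),
                          mass=mass, label=f"mode{m + 1}",
                          bin_index=(pi, pj)))
    return modes
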
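"""Membrane-binding kinetics and residue-lipid contact analysis.

Binding progress is tracked as the distance between the protein and bilayer
centres of mass per frame (full 3D or the z component, the membrane normal),
optionally averaged over a replicate ensemble, and summarised by a
single-exponential fit ``d(t) = d_inf + (d0 - d_inf) exp(-t/tau)``.

Contacts use the two definitions employed at the two resolutions of the
study: a residue is in contact when the minimum particle-particle distance
to any target lipid is below the cutoff (coarse-grained convention, 0.7 nm),
or when its COM is within the cutoff of a lipid headgroup COM (atomistic
convention, 0.35 nm).  The inequality at the cutoff is strict.  Profiles are
normalised to the residue with the largest number of contacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .core import SelectionError, Topology, Trajectory, select
from .geometry import com, min_image_displacement, unwrap

__all__ = [
    "DistanceSeries",
    "BindingFit",
    "ContactProfile",
    "ContactSeries",
    "com_distance_series",
    "ensemble_mean",
    "fit_binding_curve",
    "residue_contact_profile",
    "normalize_profile",
    "contact_timeseries",
    "count_proximal_lipids",
]

Metric = Literal["euclidean3d", "z_component"]
ContactMode = Literal["min_particle", "com"]

#: Contact cutoffs (nm) for the coarse-grained and atomistic conventions.
CG_CONTACT_CUTOFF = 0.7
AT_CONTACT_CUTOFF = 0.35
#: Radius (nm) used when counting substrate lipids proximal to an active site.
PROXIMAL_RADIUS = 3.5


@dataclass
class DistanceSeries:
    """Per-frame COM separation (nm) under a named metric."""

    times: np.ndarray
    values: np.ndarray
    metric: Metric = "euclidean3d"
    selections: dict = field(default_factory=dict)
    std: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.metric == "z_component" and np.any(self.values < 0):
            raise ValueError("z-component distances are reported as |dz| >= 0")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class BindingFit:
    """Single-exponential binding-curve fit result."""

    d0: float
    d_inf: float
    tau: float
    residual_rms: float
    converged: bool
    message: str = ""

    def __post_init__(self) -> None:
        if self.converged and self.tau <= 0:
            raise ValueError("converged fit must have tau > 0")


@dataclass
class ContactProfile:
    """Per-residue contact counts, raw and normalised to the maximum."""

    residues: np.ndarray       # simulation residue indices
    raw: np.ndarray            # integer counts
    normalized: np.ndarray     # in [0, 1]
    cutoff: float
    mode: ContactMode
    all_zero: bool = False


@dataclass
class ContactSeries:
    """Residue x frame contact occupancy (0/1 or lipid counts)."""

    residues: np.ndarray
    times: np.ndarray
    matrix: np.ndarray         # (n_residues, n_frames)
    cutoff: float
    mode: ContactMode
    per_lipid_count: bool = False


def _resolve(topology: Topology, sel) -> np.ndarray:
    if isinstance(sel, str):
        return select(topology, sel)
    ids = np.asarray(sel, dtype=int)
    return ids


def com_distance_series(traj: Trajectory, protein_sel, membrane_sel,
                        metric: Metric = "euclidean3d",
                        unwrap_molecules: bool = True) -> DistanceSeries:
    """Distance between two selections' centres of mass per frame.

    The separation vector is wrapped componentwise to the minimum image.
    ``z_component`` returns |dz| so approaches to either leaflet map
    identically.
    """
    top = traj.topology
    p_ids = _resolve(top, protein_sel)
    m_ids = _resolve(top, membrane_sel)
    if p_ids.size == 0 or m_ids.size == 0:
        raise SelectionError("empty selection for distance series")
    p_mass = top.masses[p_ids]
    m_mass = top.masses[m_ids]
    values = np.empty(len(traj))
    for i, frame in enumerate(traj.frames):
        pc = frame.coordinates[p_ids]
        mc = frame.coordinates[m_ids]
        if unwrap_molecules:
            pc = unwrap(pc, frame.box)
            mc = unwrap(mc, frame.box)
        delta = min_image_displacement(com(mc, m_mass), com(pc, p_mass),
                                       frame.box)
        if metric == "z_component":
            values[i] = abs(delta[2])
        elif metric == "euclidean3d":
            values[i] = np.linalg.norm(delta)
        else:
            raise ValueError(f"unknown metric {metric!r}")
    return DistanceSeries(times=traj.times, values=values, metric=metric,
                          selections={"protein": str(protein_sel),
                                      "membrane": str(membrane_sel)})


def ensemble_mean(series_list: Sequence[DistanceSeries],
                  with_std: bool = False,
                  resample: bool = False) -> DistanceSeries:
    """Pointwise mean over replicate distance series.

    Requires identical time grids unless *resample* is set, in which case all
    series are linearly interpolated onto the first series' grid.
    """
    if not series_list:
        raise ValueError("empty ensemble")
    ref = series_list[0]
    rows = [ref.values]
    for s in series_list[1:]:
        if s.times.shape == ref.times.shape and np.allclose(s.times, ref.times):
            rows.append(s.values)
        elif resample:
            rows.append(np.interp(ref.times, s.times, s.values))
        else:
            raise ValueError(
                "time grids differ; pass resample=True to interpolate")
    stack = np.vstack(rows)
    std = stack.std(axis=0, ddof=0) if with_std else None
    return DistanceSeries(times=ref.times.copy(), values=stack.mean(axis=0),
                          metric=ref.metric, selections=dict(ref.selections),
                          std=std)


def _exp_model(t, d_inf, d0, tau):
    return d_inf + (d0 - d_inf) * np.exp(-t / tau)


def fit_binding_curve(series: DistanceSeries) -> BindingFit:
    """Least-squares single-exponential fit of a binding curve.

    Initial guesses: d0 = first value, d_inf = last value, tau = half the
    time span; tau is constrained positive.  Non-convergence is reported in
    the result rather than raised.
    """
    t = series.times - series.times[0]
    y = series.values
    if len(t) < 4:
        raise ValueError("need at least 4 points to fit")
    if np.ptp(y) == 0:
        raise ValueError("series is constant; nothing to fit")
    span = t[-1] - t[0]
    p0 = (y[-1], y[0], span / 2.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _exp_model, t, y, p0=p0,
                bounds=([-np.inf, -np.inf, np.finfo(float).tiny],
                        [np.inf, np.inf, np.inf]),
                maxfev=10000)
    except (RuntimeError, ValueError) as exc:
        return BindingFit(d0=float(y[0]), d_inf=float(y[-1]), tau=np.nan,
                          residual_rms=np.nan, converged=False,
                          message=str(exc))
    d_inf, d0, tau = popt
    rms = float(np.sqrt(np.mean((_exp_model(t, *popt) - y) ** 2)))
    return BindingFit(d0=float(d0), d_inf=float(d_inf), tau=float(tau),
                      residual_rms=rms, converged=True)


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def _pairwise_min_image_dists(a: np.ndarray, b: np.ndarray,
                              box: np.ndarray) -> np.ndarray:
    """(len(a), len(b)) matrix of minimum-image distances."""
    delta = a[:, None, :] - b[None, :, :]
    delta -= box * np.round(delta / box)
    return np.sqrt((delta ** 2).sum(axis=-1))


def _residue_groups(topology: Topology, protein_residues) -> tuple[np.ndarray, list[np.ndarray]]:
    """Resolve a residue specification to (residue indices, particle groups).

    *protein_residues* may be None (all protein residues), a sequence of
    1-based residue indices, or a selection expression whose particles are
    grouped by residue.
    """
    if protein_residues is None:
        ids = np.flatnonzero(topology.species == "protein")
    elif isinstance(protein_residues, str):
        ids = select(topology, protein_residues)
    else:
        wanted = np.asarray(protein_residues, dtype=int)
        ids = np.flatnonzero(np.isin(topology.residue_indices, wanted)
                             & (topology.species == "protein"))
    resids = topology.residue_indices[ids]
    uniq = np.unique(resids)
    groups = [ids[resids == r] for r in uniq]
    return uniq, groups


def _lipid_groups(topology: Topology, target_ids: np.ndarray) -> list[np.ndarray]:
    resids = topology.residue_indices[target_ids]
    return [target_ids[resids == r] for r in np.unique(resids)]


def contact_timeseries(traj: Trajectory, protein_residues=None,
                       lipid_target_sel: str = "species PI4P and headgroup",
                       cutoff: float = CG_CONTACT_CUTOFF,
                       mode: ContactMode = "min_particle",
                       per_lipid_count: bool = False) -> ContactSeries:
    """Residue x frame contact occupancy against the target lipid particles.

    ``min_particle``: a residue contacts in a frame iff the minimum over all
    (residue particle, target particle) minimum-image distances is strictly
    below the cutoff.  ``com``: the residue COM must be strictly within the
    cutoff of some target lipid's headgroup COM.  With *per_lipid_count* the
    entry is the number of distinct target lipids in contact instead of 0/1.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    top = traj.topology
    residues, groups = _residue_groups(top, protein_residues)
    target_ids = _resolve(top, lipid_target_sel)
    n_frames = len(traj)
    matrix = np.zeros((len(residues), n_frames),
                      dtype=int)
    if target_ids.size == 0:
        warnings.warn("empty lipid target selection: all-zero contacts")
        return ContactSeries(residues=residues, times=traj.times,
                             matrix=matrix, cutoff=cutoff, mode=mode,
                             per_lipid_count=per_lipid_count)
    group_sizes = np.array([len(g) for g in groups])
    flat_ids = np.concatenate(groups)
    group_of = np.repeat(np.arange(len(groups)), group_sizes)
    lipid_groups = _lipid_groups(top, target_ids)
    lipid_of = np.concatenate(
        [np.full(len(g), i) for i, g in enumerate(lipid_groups)])
    lipid_flat = np.concatenate(lipid_groups)
    n_lip = len(lipid_groups)
    lipid_masses = top.masses[lipid_flat]

    for fi, frame in enumerate(traj.frames):
        box = frame.box
        if mode == "min_particle":
            dists = _pairwise_min_image_dists(
                frame.coordinates[flat_ids], frame.coordinates[lipid_flat], box)
            hit = dists < cutoff
            if per_lipid_count:
                # residue-lipid pair in contact if any particle pair is
                pair = np.zeros((len(groups), n_lip), dtype=int)
                np.add.at(pair, (group_of[:, None], lipid_of[None, :]), hit)
                matrix[:, fi] = (pair > 0).sum(axis=1)
            else:
                res_hit = np.zeros(len(groups), dtype=bool)
                np.logical_or.at(res_hit, group_of, hit.any(axis=1))
                matrix[:, fi] = res_hit
        elif mode == "com":
            res_coms = np.array([
                com(unwrap(frame.coordinates[g], box), top.masses[g])
                for g in groups])
            lip_coms = np.array([
                com(unwrap(frame.coordinates[g], box), top.masses[g])
                for g in lipid_groups])
            dists = _pairwise_min_image_dists(res_coms, lip_coms, box)
            hit = dists < cutoff
            matrix[:, fi] = hit.sum(axis=1) if per_lipid_count else hit.any(axis=1)
        else:
            raise ValueError(f"unknown contact mode {mode!r}")
    return ContactSeries(residues=residues, times=traj.times, matrix=matrix,
                         cutoff=cutoff, mode=mode,
                         per_lipid_count=per_lipid_count)


def residue_contact_profile(traj: Trajectory, protein_residues=None,
                            lipid_target_sel: str = "species PI4P and headgroup",
                            cutoff: float = CG_CONTACT_CUTOFF,
                            mode: ContactMode = "min_particle",
                            per_lipid_count: bool = False) -> ContactProfile:
    """Total contacts per residue over the trajectory, normalised to the
    residue with the largest number of contacts."""
    series = contact_timeseries(traj, protein_residues, lipid_target_sel,
                                cutoff, mode, per_lipid_count)
    raw = series.matrix.sum(axis=1)
    profile = ContactProfile(residues=series.residues, raw=raw,
                             normalized=np.zeros_like(raw, dtype=float),
                             cutoff=cutoff, mode=mode)
    return normalize_profile(profile)


def normalize_profile(profile: ContactProfile) -> ContactProfile:
    """Normalise raw counts to the residue with the largest count; an
    all-zero profile stays zero and is flagged."""
    raw = np.asarray(profile.raw)
    peak = raw.max(initial=0)
    if peak == 0:
        return ContactProfile(residues=profile.residues, raw=raw,
                              normalized=np.zeros(len(raw)),
                              cutoff=profile.cutoff, mode=profile.mode,
                              all_zero=True)
    return ContactProfile(residues=profile.residues, raw=raw,
                          normalized=raw / peak, cutoff=profile.cutoff,
                          mode=profile.mode, all_zero=False)


def count_proximal_lipids(traj: Trajectory, site_sel, lipid_sel,
                          radius: float = PROXIMAL_RADIUS) -> np.ndarray:
    """Per-frame number of lipids whose headgroup COM lies strictly within
    *radius* nm (minimum image) of the site selection's COM."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    top = traj.topology
    site_ids = _resolve(top, site_sel)
    if site_ids.size == 0:
        raise SelectionError("empty site selection")
    target_ids = _resolve(top, lipid_sel)
    lipid_groups = _lipid_groups(top, target_ids)
    counts = np.zeros(len(traj), dtype=int)
    if not lipid_groups:
        return counts
    site_masses = top.masses[site_ids]
    for fi, frame in enumerate(traj.frames):
        box = frame.box
        site_com = com(unwrap(frame.coordinates[site_ids], box), site_masses)
        lip_coms = np.array([
            com(unwrap(frame.coordinates[g], box), top.masses[g])
            for g in lipid_groups])
        d = _pairwise_min_image_dists(site_com[None, :], lip_coms, box)[0]
        counts[fi] = int((d < radius).sum())
    return counts
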
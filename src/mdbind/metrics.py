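"""Structural observables: superposition, RMSD, RMSF, Rg, SASA, hydrogen bonds.

All metrics operate on :class:`~mdbind.io.ConformationalEnsemble` objects and
are invariant under a global rigid motion applied uniformly to every frame.
Hydrogen bonds follow the standard geometric criterion used in trajectory
post-processing: donor...acceptor distance < 3.5 A and donor-H...acceptor
angle > 120 deg (measured at the hydrogen), with occupancy the percentage of
frames in which both hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .io import ConformationalEnsemble, Topology

__all__ = [
    "Superposition",
    "HBondSpec",
    "HBondResult",
    "SeriesSummary",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf",
    "radius_of_gyration",
    "sasa",
    "detect_hbonds",
    "series_summary",
]


@dataclass
class Superposition:
    rotation: np.ndarray      # (3, 3), orthonormal, det +1
    translation: np.ndarray   # (3,)
    rmsd: float               # post-fit, A
    selection: str = "all"


@dataclass
class HBondSpec:
    """Candidate hydrogen bond: donor heavy atom, its hydrogen, acceptor."""

    donor: int
    hydrogen: int
    acceptor: int
    distance_cutoff: float = 3.5   # A, donor...acceptor, strict <
    angle_cutoff: float = 120.0    # deg, donor-H...acceptor, strict >
    label: str = ""

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0.0 < self.angle_cutoff < 180.0:
            raise ValueError("angle cutoff must be in (0, 180) deg")


@dataclass
class HBondResult:
    spec: HBondSpec
    present: np.ndarray        # (F,) bool
    occupancy: float           # %
    mean_distance: float       # A over present frames (nan if never present)
    mean_angle: float          # deg over present frames


@dataclass
class SeriesSummary:
    values: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray
    peaks: np.ndarray = field(default_factory=lambda: np.array([]))  # bin centers


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     selection: str = "all") -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(R, t, rmsd, aligned)`` with ``aligned = mobile @ R.T + t``.
    Requires at least 3 non-collinear atoms.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (A, 3)")
    if mobile.shape[0] < 3:
        raise ValueError("superposition needs at least 3 atoms")
    mob_c = mobile - mobile.mean(axis=0)
    if np.linalg.matrix_rank(mob_c, tol=1e-8) < 2:
        raise ValueError("superposition needs at least 3 non-collinear atoms")
    ref_c = reference - reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    r = rot.as_matrix()
    t = reference.mean(axis=0) - mobile.mean(axis=0) @ r.T
    aligned = mobile @ r.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((aligned - reference) ** 2, axis=1))))
    return r, t, rmsd, aligned


def rmsd_series(ensemble: ConformationalEnsemble, reference: np.ndarray,
                selection: str = "backbone", n_bins: int = 50) -> SeriesSummary:
    """Per-frame best-fit RMSD of a selection against a reference frame."""
    idx = ensemble.topology.select(selection)
    if len(idx) == 0:
        raise ValueError(f"selection {selection!r} matches no atoms")
    ref = np.asarray(reference, float)[idx]
    values = np.array([
        kabsch_superpose(ensemble.coords[f][idx], ref)[2]
        for f in range(ensemble.n_frames)
    ])
    return series_summary(values, n_bins)


def _iterative_mean(coords: np.ndarray, rounds: int = 2) -> np.ndarray:
    """Superpose frames to an iteratively refined mean structure."""
    work = coords.copy()
    ref = work[0]
    for _ in range(rounds):
        for f in range(work.shape[0]):
            work[f] = kabsch_superpose(work[f], ref)[3]
        ref = work.mean(axis=0)
    return work


def rmsf(ensemble: ConformationalEnsemble, selection: str = "calpha",
         superpose: bool = True) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the mean structure.

    Frames are first superposed onto their iterative mean (2 rounds) unless
    ``superpose=False`` (useful for closed-form checks on constructed data).
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    idx = ensemble.topology.select(selection)
    if len(idx) == 0:
        raise ValueError(f"selection {selection!r} matches no atoms")
    coords = ensemble.coords[:, idx].copy()
    if superpose:
        coords = _iterative_mean(coords)
    mean = coords.mean(axis=0)
    return np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))


def radius_of_gyration(coords: np.ndarray, topology: Topology) -> float:
    """Mass-weighted radius of gyration (unit masses if none supplied)."""
    masses = topology.mass if topology.mass is not None else np.ones(topology.n_atoms)
    total = masses.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    com = (masses[:, None] * coords).sum(axis=0) / total
    return float(np.sqrt((masses * np.sum((coords - com) ** 2, axis=1)).sum() / total))


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5 ** 0.5) * k
    return np.column_stack([
        np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)
    ])


def sasa(coords: np.ndarray, topology: Topology, probe: float = 1.4,
         n_points: int = 960, radii: np.ndarray | None = None,
         subset: np.ndarray | None = None) -> tuple[float, np.ndarray]:
    """Shrake-Rupley solvent-accessible surface area.

    Radii come from the topology parameter table (``born_radius`` doubles as
    the vdW radius source unless ``radii`` is given).  Returns the total area
    and the per-atom areas (A^2).  ``subset`` restricts both the reported atoms
    and the occluders to an index set, which is how the bound/free difference
    of the nonpolar solvation term is computed.
    """
    if radii is None:
        if topology.born_radius is None:
            raise ValueError("no per-atom radii available")
        radii = topology.born_radius
    radii = np.asarray(radii, float)
    if np.any(radii <= 0):
        raise ValueError("all atom radii must be positive")
    if subset is None:
        subset = np.arange(topology.n_atoms)
    pts = _sphere_points(n_points)
    xyz = coords[subset]
    rr = radii[subset] + probe
    per_atom = np.zeros(len(subset))
    for a in range(len(subset)):
        test = xyz[a] + rr[a] * pts
        others = np.delete(np.arange(len(subset)), a)
        if len(others):
            neigh = others[np.linalg.norm(xyz[others] - xyz[a], axis=1) < rr[a] + rr[others]]
        else:
            neigh = others
        exposed = np.ones(n_points, dtype=bool)
        for b in neigh:
            exposed &= np.linalg.norm(test - xyz[b], axis=1) >= rr[b]
            if not exposed.any():
                break
        per_atom[a] = exposed.mean() * 4 * np.pi * rr[a] ** 2
    return float(per_atom.sum()), per_atom


def detect_hbonds(ensemble: ConformationalEnsemble,
                  specs: list[HBondSpec]) -> list[HBondResult]:
    """Geometric hydrogen-bond detection with per-frame presence and occupancy."""
    n_atoms = ensemble.n_atoms
    results = []
    for spec in specs:
        for atom in (spec.donor, spec.hydrogen, spec.acceptor):
            if not 0 <= atom < n_atoms:
                raise ValueError(f"hydrogen-bond spec references missing atom {atom}")
        d = ensemble.coords[:, spec.donor]
        h = ensemble.coords[:, spec.hydrogen]
        a = ensemble.coords[:, spec.acceptor]
        dist = np.linalg.norm(a - d, axis=1)
        v1 = d - h
        v2 = a - h
        cosang = np.sum(v1 * v2, axis=1) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
        )
        angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        present = (dist < spec.distance_cutoff) & (angle > spec.angle_cutoff)
        occupancy = 100.0 * present.sum() / ensemble.n_frames
        results.append(HBondResult(
            spec=spec,
            present=present,
            occupancy=float(occupancy),
            mean_distance=float(dist[present].mean()) if present.any() else float("nan"),
            mean_angle=float(angle[present].mean()) if present.any() else float("nan"),
        ))
    return results


def series_summary(values: np.ndarray, n_bins: int = 50) -> SeriesSummary:
    """Histogram a per-frame series and locate its frequency-distribution peaks.

    Peaks are local maxima of the counts after a centered 3-bin moving average;
    ties are broken toward the lower value.
    """
    values = np.asarray(values, float)
    if values.size < 1:
        raise ValueError("series is empty")
    counts, edges = np.histogram(values, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    padded = np.pad(counts.astype(float), 1, mode="edge")
    smooth = (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0
    peaks = []
    # walk maximal plateaus of the smoothed counts; a plateau strictly above
    # both its flanks is one peak, reported at its lowest occupied bin
    i = 0
    while i < len(smooth):
        j = i
        while j + 1 < len(smooth) and smooth[j + 1] == smooth[i]:
            j += 1
        left = smooth[i - 1] if i > 0 else -np.inf
        right = smooth[j + 1] if j + 1 < len(smooth) else -np.inf
        if smooth[i] > left and smooth[i] > right:
            occupied = [k for k in range(i, j + 1) if counts[k] > 0]
            if occupied:
                peaks.append(centers[occupied[0]])
        i = j + 1
    return SeriesSummary(values=values, bin_edges=edges, counts=counts,
                         peaks=np.array(peaks))
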
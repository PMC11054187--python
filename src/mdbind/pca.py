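"""Principal component analysis of C-alpha coordinates and free-energy landscapes.

The covariance of superposed C-alpha coordinates, C = <(q - <q>)(q - <q>)^T>,
is diagonalized to obtain collective-motion eigenvectors; projections of the
trajectory onto the first two eigenvectors serve as reaction coordinates for a
2D free-energy landscape via Boltzmann inversion,
G(bin) = -kT ln(P(bin)/P_max), with the populated minimum at exactly zero.
Covariance is normalized by the number of frames F (a population average, not
F-1), and frames are superposed to their iterative mean structure first so
only internal motion enters C.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ConformationalEnsemble
from .metrics import kabsch_superpose

__all__ = [
    "PCAModel",
    "FELGrid",
    "Basin",
    "BasinSet",
    "KB_KCAL",
    "build_pca",
    "variance_fractions",
    "project",
    "free_energy_landscape",
    "find_basins",
    "mode_displacements",
]

KB_KCAL = 0.0019872     # kcal mol^-1 K^-1


@dataclass
class PCAModel:
    mean: np.ndarray               # (3M,)
    covariance: np.ndarray         # (3M, 3M)
    eigenvalues: np.ndarray        # descending, A^2
    eigenvectors: np.ndarray       # columns, orthonormal
    reference: np.ndarray          # (M, 3) superposition reference
    selection: str = "calpha"
    superposed: bool = True

    @property
    def n_atoms(self) -> int:
        return self.mean.size // 3


@dataclass
class FELGrid:
    x_edges: np.ndarray
    y_edges: np.ndarray
    probability: np.ndarray        # sums to 1
    free_energy: np.ndarray        # kcal/mol, min over populated bins = 0
    temperature: float
    kt: float
    sentinel: float                # G assigned to empty bins
    n_samples: int = 0


@dataclass
class Basin:
    basin_id: int
    min_bin: tuple[int, int]
    min_energy: float
    member_bins: list[tuple[int, int]] = field(default_factory=list)
    representative_frame: int | None = None


@dataclass
class BasinSet:
    basins: list[Basin]

    def __len__(self) -> int:
        return len(self.basins)


def _superposed_coords(ensemble: ConformationalEnsemble, selection: str,
                       superpose: bool, reference: np.ndarray | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    idx = ensemble.topology.select(selection)
    if len(idx) == 0:
        raise ValueError(f"selection {selection!r} matches no atoms")
    coords = ensemble.coords[:, idx].copy()
    if not superpose:
        return coords, coords.mean(axis=0)
    if reference is None:
        ref = coords[0]
        for _ in range(2):
            for f in range(coords.shape[0]):
                coords[f] = kabsch_superpose(coords[f], ref)[3]
            ref = coords.mean(axis=0)
    else:
        ref = reference
        for f in range(coords.shape[0]):
            coords[f] = kabsch_superpose(coords[f], ref)[3]
    return coords, ref


def build_pca(ensemble: ConformationalEnsemble, selection: str = "calpha",
              superpose: bool = True) -> PCAModel:
    """Diagonalize the (superposed) coordinate covariance; F-normalized."""
    if ensemble.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    coords, ref = _superposed_coords(ensemble, selection, superpose)
    x = coords.reshape(ensemble.n_frames, -1)
    mean = x.mean(axis=0)
    xc = x - mean
    cov = (xc.T @ xc) / x.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    return PCAModel(mean=mean, covariance=cov, eigenvalues=evals,
                    eigenvectors=evecs, reference=ref, selection=selection,
                    superposed=superpose)


def variance_fractions(model: PCAModel, k: int) -> tuple[np.ndarray, float]:
    """Per-mode variance fractions (%) for the first k modes and their cumulative (%)."""
    if k > model.eigenvalues.size:
        raise ValueError(f"k={k} exceeds the {model.eigenvalues.size} available modes")
    total = model.eigenvalues.sum()
    if total <= 0:
        raise ValueError("zero total variance")
    fractions = 100.0 * model.eigenvalues[:k] / total
    return fractions, float(fractions.sum())


def project(ensemble: ConformationalEnsemble, model: PCAModel, k: int = 2) -> np.ndarray:
    """(F, k) projections onto the leading eigenvectors, in the model's frame."""
    coords, _ = _superposed_coords(ensemble, model.selection, model.superposed,
                                   reference=model.reference)
    x = coords.reshape(ensemble.n_frames, -1)
    if x.shape[1] != model.mean.size:
        raise ValueError("ensemble selection does not match the PCA model")
    return (x - model.mean) @ model.eigenvectors[:, :k]


def free_energy_landscape(projections: np.ndarray, bins: int = 100,
                          temperature: float = 300.0) -> FELGrid:
    """Boltzmann inversion of the binned PC1/PC2 density."""
    projections = np.asarray(projections, float)
    if projections.size == 0:
        raise ValueError("no projections to bin")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    counts, xe, ye = np.histogram2d(projections[:, 0], projections[:, 1], bins=bins)
    prob = counts / counts.sum()
    kt = KB_KCAL * temperature
    populated = prob > 0
    g = np.full_like(prob, np.nan)
    g[populated] = -kt * np.log(prob[populated] / prob.max())
    sentinel = float(np.nanmax(g)) + 1.0
    g[~populated] = sentinel
    return FELGrid(x_edges=xe, y_edges=ye, probability=prob, free_energy=g,
                   temperature=temperature, kt=kt, sentinel=sentinel,
                   n_samples=int(counts.sum()))


def find_basins(grid: FELGrid, depth_threshold: float = 0.5,
                projections: np.ndarray | None = None,
                min_count: float = 2.0, smooth: bool = True) -> BasinSet:
    """Energy basins: 8-neighborhood local minima merged across shallow barriers.

    Bin counts are first smoothed with a 3x3 box filter (``smooth=True``),
    which suppresses the Poisson minima that sparse occupancy would otherwise
    each promote to a basin; bins whose (smoothed) count is below
    ``min_count`` are treated as unpopulated.  The remaining bins are flooded
    in order of increasing free energy; a bin touching no assigned neighbor
    seeds a new basin, and when a bin bridges two basins they merge if the
    barrier above the shallower minimum is below ``depth_threshold``
    (kcal/mol).  If ``projections`` are given, each basin records the frame
    closest to its minimum bin center in PC space.
    """
    counts = grid.probability * max(grid.n_samples, 1)
    if smooth:
        p = np.pad(counts, 1)
        counts = sum(p[i:i + counts.shape[0], j:j + counts.shape[1]]
                     for i in range(3) for j in range(3)) / 9.0
    populated = counts >= min_count
    if not populated.any():
        populated = grid.probability > 0
    g = np.full_like(counts, np.inf)
    g[populated] = -grid.kt * np.log(counts[populated] / counts.max())
    order = sorted(zip(*np.nonzero(populated)), key=lambda b: (g[b], b))
    label = -np.ones(g.shape, dtype=int)
    minima: dict[int, tuple[tuple[int, int], float]] = {}
    merged_into: dict[int, int] = {}

    def root(lbl: int) -> int:
        while lbl in merged_into:
            lbl = merged_into[lbl]
        return lbl

    next_label = 0
    nx, ny = g.shape
    for (i, j) in order:
        neigh_labels = set()
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == dj == 0:
                    continue
                a, b = i + di, j + dj
                if 0 <= a < nx and 0 <= b < ny and label[a, b] >= 0:
                    neigh_labels.add(root(label[a, b]))
        if not neigh_labels:
            label[i, j] = next_label
            minima[next_label] = ((i, j), float(g[i, j]))
            next_label += 1
        elif len(neigh_labels) == 1:
            label[i, j] = neigh_labels.pop()
        else:
            ordered = sorted(neigh_labels, key=lambda l: (minima[l][1], minima[l][0]))
            keep = ordered[0]
            for other in ordered[1:]:
                # barrier height above the shallower of the two minima
                if g[i, j] - minima[other][1] < depth_threshold:
                    merged_into[other] = keep
            label[i, j] = keep

    final: dict[int, Basin] = {}
    for (i, j) in zip(*np.nonzero(populated)):
        lbl = root(label[i, j])
        if lbl not in final:
            mi, mj = minima[lbl][0]
            final[lbl] = Basin(basin_id=len(final), min_bin=(int(mi), int(mj)),
                               min_energy=float(minima[lbl][1]))
        final[lbl].member_bins.append((int(i), int(j)))

    basins = sorted(final.values(), key=lambda b: (b.min_energy, b.min_bin))
    for new_id, basin in enumerate(basins):
        basin.basin_id = new_id
        if projections is not None:
            xc = 0.5 * (grid.x_edges[basin.min_bin[0]] + grid.x_edges[basin.min_bin[0] + 1])
            yc = 0.5 * (grid.y_edges[basin.min_bin[1]] + grid.y_edges[basin.min_bin[1] + 1])
            d = np.linalg.norm(projections[:, :2] - np.array([xc, yc]), axis=1)
            basin.representative_frame = int(np.argmin(d))
    return BasinSet(basins)


def mode_displacements(model: PCAModel, k: int = 0) -> np.ndarray:
    """Per-residue displacement magnitude of eigenvector ``k`` (0-based)."""
    if k >= model.eigenvectors.shape[1]:
        raise ValueError(f"mode {k} not available")
    vec = model.eigenvectors[:, k].reshape(-1, 3)
    return np.linalg.norm(vec, axis=1)
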
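"""Residue contact maps and their image encoding for classification.

A frame becomes an ``N x N`` binary matrix: residues i and j are in contact
when the selected atoms (C-alpha by default, or closest heavy atoms) are within
an inclusive distance cutoff, 4.5 A by default.  Contact matrices are encoded
one-to-one as grayscale images (contact = 1.0, background = 0.0) and split
80/20 per class into training and validation sets for the CNN.

The saliency stage needs one *representative* contact map per system: frames
are clustered on pairwise C-alpha RMSD (average linkage) and the medoid of the
most populated cluster is returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform

from .io import ConformationalEnsemble, Topology
from .metrics import kabsch_superpose

__all__ = [
    "ContactMapStack",
    "ImageDataset",
    "contact_map",
    "contact_maps",
    "maps_to_images",
    "split_train_val",
    "most_populated_representative",
]


@dataclass
class ContactMapStack:
    maps: np.ndarray          # (F, N, N) uint8, symmetric, unit diagonal
    cutoff: float
    atom_rule: str

    def __post_init__(self) -> None:
        if self.maps.ndim != 3 or self.maps.shape[1] != self.maps.shape[2]:
            raise ValueError("maps must have shape (F, N, N)")

    @property
    def n_residues(self) -> int:
        return self.maps.shape[1]


@dataclass
class ImageDataset:
    """Grayscale images with labels and an optional stratified split."""

    images: np.ndarray                    # (F, N, N) float in [0, 1]
    labels: np.ndarray | None = None
    train_idx: np.ndarray | None = None
    val_idx: np.ndarray | None = None
    split_seed: int | None = None

    @property
    def n_images(self) -> int:
        return self.images.shape[0]


def _residue_coords(coords: np.ndarray, topology: Topology, atom_rule: str):
    """Per-residue coordinate selection for the contact rule."""
    spans = topology.residue_atom_indices()
    if atom_rule == "calpha":
        sel = []
        for r, span in enumerate(spans):
            ca = [a for a in span if topology.atom_names[a] == "CA"]
            if not ca:
                rid = topology.residue_ids()[r]
                raise ValueError(f"residue {rid} has no CA atom")
            sel.append(ca[0])
        return coords[np.array(sel)], None
    if atom_rule == "closest-heavy":
        heavy_spans = []
        for r, span in enumerate(spans):
            heavy = [a for a in span if topology.elements[a].upper() != "H"]
            if not heavy:
                rid = topology.residue_ids()[r]
                raise ValueError(f"residue {rid} has no heavy atom")
            heavy_spans.append(np.array(heavy))
        return None, heavy_spans
    raise ValueError(f"unknown atom rule {atom_rule!r}")


def contact_map(coords: np.ndarray, topology: Topology, cutoff: float = 4.5,
                atom_rule: str = "calpha") -> np.ndarray:
    """Binary residue contact matrix of one frame (cutoff inclusive)."""
    ca, heavy_spans = _residue_coords(coords, topology, atom_rule)
    n = topology.n_residues
    if ca is not None:
        dist = cdist(ca, ca)
    else:
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = cdist(coords[heavy_spans[i]], coords[heavy_spans[j]]).min()
                dist[i, j] = dist[j, i] = d
    return (dist <= cutoff).astype(np.uint8)


def contact_maps(ensemble: ConformationalEnsemble, cutoff: float = 4.5,
                 atom_rule: str = "calpha") -> ContactMapStack:
    """Per-frame contact matrices of an ensemble."""
    maps = np.stack([
        contact_map(ensemble.coords[f], ensemble.topology, cutoff, atom_rule)
        for f in range(ensemble.n_frames)
    ])
    return ContactMapStack(maps, cutoff, atom_rule)


def maps_to_images(stack: ContactMapStack) -> ImageDataset:
    """Encode contact matrices as grayscale images (contact = 1.0)."""
    return ImageDataset(images=stack.maps.astype(np.float64))


def split_train_val(dataset: ImageDataset, fraction: float = 0.8,
                    seed: int = 0) -> ImageDataset:
    """Stratified train/validation split: ``fraction`` of *each class* trains.

    Deterministic under ``seed``; every class must keep at least one image on
    each side of the split.
    """
    if dataset.labels is None:
        raise ValueError("dataset has no labels")
    labels = np.asarray(dataset.labels)
    rng = np.random.default_rng(seed)
    train, val = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls} has fewer than 2 images")
        n_train = int(round(fraction * len(idx)))
        if n_train < 1 or n_train >= len(idx):
            raise ValueError(
                f"fraction {fraction} leaves an empty split for class {cls}"
            )
        perm = rng.permutation(idx)
        train.append(perm[:n_train])
        val.append(perm[n_train:])
    dataset.train_idx = np.sort(np.concatenate(train))
    dataset.val_idx = np.sort(np.concatenate(val))
    dataset.split_seed = seed
    return dataset


def _pairwise_ca_rmsd(coords: np.ndarray) -> np.ndarray:
    """Condensed pairwise best-fit RMSD matrix over frames of C-alpha coords."""
    f = coords.shape[0]
    centered = coords - coords.mean(axis=1, keepdims=True)
    out = np.zeros(f * (f - 1) // 2)
    k = 0
    for i in range(f):
        for j in range(i + 1, f):
            _, _, rmsd, _ = kabsch_superpose(centered[i], centered[j])
            out[k] = rmsd
            k += 1
    return out


def most_populated_representative(
    ensemble: ConformationalEnsemble,
    rmsd_cut: float = 2.0,
    cutoff: float = 4.5,
    atom_rule: str = "calpha",
    max_frames: int = 200,
    seed: int = 0,
) -> tuple[int, np.ndarray]:
    """Frame index and contact map of the most populated structural cluster.

    Frames (subsampled to at most ``max_frames`` by even stride for tractable
    pairwise RMSD) are clustered by average linkage on pairwise C-alpha RMSD
    and cut at ``rmsd_cut`` A.  The representative is the medoid of the largest
    cluster (frame minimizing summed within-cluster RMSD); ties in cluster size
    and in medoid cost are broken toward the lower frame index.
    """
    ca_idx = ensemble.topology.select("calpha")
    if len(ca_idx) == 0:
        raise ValueError("no C-alpha atoms in topology")
    stride = max(1, int(np.ceil(ensemble.n_frames / max_frames)))
    frame_ids = np.arange(0, ensemble.n_frames, stride)
    coords = ensemble.coords[frame_ids][:, ca_idx]
    if len(frame_ids) == 1:
        rep = int(frame_ids[0])
        return rep, contact_map(ensemble.coords[rep], ensemble.topology, cutoff, atom_rule)
    condensed = _pairwise_ca_rmsd(coords)
    if np.allclose(condensed, 0.0):
        rep = int(frame_ids[0])
        return rep, contact_map(ensemble.coords[rep], ensemble.topology, cutoff, atom_rule)
    labels = fcluster(linkage(condensed, method="average"), t=rmsd_cut, criterion="distance")
    sizes = np.bincount(labels)
    # ties in cluster size resolve to the cluster holding the earliest frame
    candidates = np.flatnonzero(sizes == sizes.max())
    best = min(candidates, key=lambda c: int(np.flatnonzero(labels == c)[0]))
    members = np.flatnonzero(labels == best)
    dmat = squareform(condensed)
    costs = dmat[np.ix_(members, members)].sum(axis=1)
    medoid = members[int(np.flatnonzero(costs == costs.min())[0])]
    rep = int(frame_ids[medoid])
    return rep, contact_map(ensemble.coords[rep], ensemble.topology, cutoff, atom_rule)
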
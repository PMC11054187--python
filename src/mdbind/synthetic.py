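"""Synthetic conformational ensembles with planted, recoverable structure.

Real applications of this pipeline start from hundreds of nanoseconds of MD on
an inhibitor-bound protein.  For testing, that sampling is replaced by K-class
ensembles built around C-alpha-only reference chains in which each class is
distinguished by a small set of *planted* residue-residue contacts:

* consecutive C-alpha beads are 3.8 A apart (the trans peptide virtual bond);
* for class k, exactly the planted pairs of class k sit at <= 4.0 A;
* every other non-neighbor pair is kept > 5.5 A,

so a 4.5 A contact cutoff separates planted contacts from background with a
wide margin.  Frames are drawn by adding isotropic Gaussian noise about the
class reference -- no kinetics, which is what makes every downstream result
analytically checkable.

A toy ligand-receptor complex with charges, LJ and Born parameters is provided
for the binding free-energy stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .io import ConformationalEnsemble, DomainAnnotation, Topology

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "default_domains",
    "default_benchmark_spec",
    "generate_reference_structures",
    "sample_ensemble",
    "generate_class_ensembles",
    "generate_ligand_system",
]

BOND_LENGTH = 3.8       # A, consecutive C-alpha spacing
CONTACT_TARGET = 3.5    # A, planted pairs are pulled to this distance
CONTACT_MAX = 4.0       # A, verification bound for planted pairs
EXCLUDED_MIN = 5.5      # A, verification bound for non-planted non-neighbor pairs
REPULSION_TARGET = 5.6  # A, optimization keeps background pairs beyond this


@dataclass
class SyntheticSpec:
    """Study conditions for a planted-contact classification benchmark."""

    n_residues: int = 40
    domains: DomainAnnotation | None = None
    class_contacts: list[set[tuple[int, int]]] = field(default_factory=list)  # 1-based pairs
    noise_sigma: float = 0.3         # A per coordinate
    frames_per_class: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.class_contacts) < 2:
            raise ValueError("at least K=2 classes are required")
        if self.noise_sigma <= 0:
            raise ValueError("noise sigma must be > 0")
        for k, pairs in enumerate(self.class_contacts):
            for i, j in pairs:
                if not (1 <= i <= self.n_residues and 1 <= j <= self.n_residues):
                    raise ValueError(f"class {k}: planted pair ({i}, {j}) outside chain")
                if abs(i - j) < 3:
                    raise ValueError(
                        f"class {k}: planted pair ({i}, {j}) too close in sequence"
                    )
        canon = [frozenset(tuple(sorted(p)) for p in pairs) for pairs in self.class_contacts]
        for a in range(len(canon)):
            for b in range(a + 1, len(canon)):
                if canon[a] == canon[b]:
                    raise ValueError(
                        f"classes {a} and {b} have identical planted contact sets; "
                        "classes are indistinguishable"
                    )

    @property
    def n_classes(self) -> int:
        return len(self.class_contacts)


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery checks."""

    labels: np.ndarray                                  # class id per frame
    planted_pairs: list[list[tuple[int, int]]]          # 1-based, per class
    discriminative_pairs: list[list[tuple[int, int]]]   # pairs unique to each class
    basin_centers: np.ndarray | None = None


def default_domains(n_residues: int = 40, n_domains: int = 4) -> DomainAnnotation:
    """Evenly tiled structural domains D1..Dn over the chain."""
    edges = np.linspace(0, n_residues, n_domains + 1).astype(int)
    return DomainAnnotation([
        (f"D{k + 1}", int(edges[k]) + 1, int(edges[k + 1]))
        for k in range(n_domains)
    ])


def default_benchmark_spec(n_residues: int = 40, frames_per_class: int = 300,
                           noise_sigma: float = 0.3, seed: int = 0) -> SyntheticSpec:
    """The standard 3-class benchmark: one unique planted contact per class.

    The planted contacts bridge distinct, non-adjacent domain pairs (D1-D3,
    D2-D4, D1-D4 for the default 40-residue, 4-domain layout), so saliency
    aggregated over domain pairs has an unambiguous ground-truth answer.
    """
    q = n_residues // 4
    pairs = [
        {(q // 2, 2 * q + q // 2)},           # mid-D1 with mid-D3
        {(q + q // 2, 3 * q + q // 2)},       # mid-D2 with mid-D4
        {(q // 2 + 1, 3 * q + q // 2 + 1)},   # D1 with D4
    ]
    return SyntheticSpec(
        n_residues=n_residues,
        domains=default_domains(n_residues),
        class_contacts=pairs,
        noise_sigma=noise_sigma,
        frames_per_class=frames_per_class,
        seed=seed,
    )


def _chain_topology(n_residues: int, prefix: str = "GLY") -> Topology:
    return Topology(
        atom_names=["CA"] * n_residues,
        elements=["C"] * n_residues,
        res_ids=np.arange(1, n_residues + 1),
        res_names=[prefix] * n_residues,
        chain_ids=["A"] * n_residues,
    )


def _chain_energy_grad(x: np.ndarray, n: int, planted: np.ndarray,
                       background: np.ndarray) -> tuple[float, np.ndarray]:
    """Penalty energy and gradient for the pull-and-relax chain builder."""
    coords = x.reshape(n, 3)
    grad = np.zeros_like(coords)
    energy = 0.0

    def pair_terms(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        d = coords[idx[:, 0]] - coords[idx[:, 1]]
        r = np.linalg.norm(d, axis=1)
        return d, r

    # bonds: harmonic about 3.8 A
    bonds = np.column_stack([np.arange(n - 1), np.arange(1, n)])
    d, r = pair_terms(bonds)
    dev = r - BOND_LENGTH
    energy += 10.0 * np.sum(dev ** 2)
    g = (20.0 * dev / r)[:, None] * d
    np.add.at(grad, bonds[:, 0], g)
    np.add.at(grad, bonds[:, 1], -g)

    # planted contacts: one-sided pull toward <= CONTACT_TARGET
    if len(planted):
        d, r = pair_terms(planted)
        dev = np.maximum(r - CONTACT_TARGET, 0.0)
        energy += 5.0 * np.sum(dev ** 2)
        g = (10.0 * dev / r)[:, None] * d
        np.add.at(grad, planted[:, 0], g)
        np.add.at(grad, planted[:, 1], -g)

    # background pairs: one-sided repulsion beyond REPULSION_TARGET
    if len(background):
        d, r = pair_terms(background)
        dev = np.maximum(REPULSION_TARGET - r, 0.0)
        energy += 5.0 * np.sum(dev ** 2)
        g = (-10.0 * dev / np.maximum(r, 1e-6))[:, None] * d
        np.add.at(grad, background[:, 0], g)
        np.add.at(grad, background[:, 1], -g)

    return energy, grad.ravel()


def _build_reference(n: int, planted_pairs: set[tuple[int, int]], rng: np.random.Generator,
                     max_attempts: int = 60) -> np.ndarray:
    """Fold a self-avoiding C-alpha chain realizing exactly the planted contacts."""
    planted0 = {tuple(sorted((i - 1, j - 1))) for i, j in planted_pairs}
    planted = np.array(sorted(planted0), dtype=int).reshape(-1, 2)
    background = np.array(
        [(i, j) for i in range(n) for j in range(i + 2, n)
         if (i, j) not in planted0],
        dtype=int,
    )
    for _ in range(max_attempts):
        # extended chain + jitter: all |i-j|>=2 pairs start >= 2*3.8 A apart
        coords = np.zeros((n, 3))
        coords[:, 0] = np.arange(n) * BOND_LENGTH
        coords += rng.normal(scale=0.4, size=(n, 3))
        res = minimize(
            _chain_energy_grad, coords.ravel(), args=(n, planted, background),
            jac=True, method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-10},
        )
        c = res.x.reshape(n, 3)
        bond_r = np.linalg.norm(np.diff(c, axis=0), axis=1)
        if np.any(np.abs(bond_r - BOND_LENGTH) > 0.15):
            continue
        ok = True
        if len(planted):
            pr = np.linalg.norm(c[planted[:, 0]] - c[planted[:, 1]], axis=1)
            ok &= bool(np.all(pr <= CONTACT_MAX))
        if len(background):
            br = np.linalg.norm(c[background[:, 0]] - c[background[:, 1]], axis=1)
            ok &= bool(np.all(br > EXCLUDED_MIN))
        if ok:
            return c - c.mean(axis=0)
    raise RuntimeError(
        f"could not realize {len(planted)} planted contacts on a {n}-residue chain "
        f"after {max_attempts} attempts; the geometry is likely infeasible"
    )


def generate_reference_structures(
    spec: SyntheticSpec,
) -> tuple[list[ConformationalEnsemble], GroundTruth]:
    """One single-frame reference ensemble per class, plus ground truth.

    Deterministic given ``spec.seed``.  Raises if two classes share identical
    planted sets or if the requested contacts cannot be realized geometrically.
    """
    rng = np.random.default_rng(spec.seed)
    topo = _chain_topology(spec.n_residues)
    refs = []
    for k, pairs in enumerate(spec.class_contacts):
        coords = _build_reference(spec.n_residues, set(pairs), rng)
        refs.append(ConformationalEnsemble(topo, coords[None], [(f"ref{k}", 0)]))

    canon = [set(tuple(sorted(p)) for p in pairs) for pairs in spec.class_contacts]
    discriminative = []
    for k, pairs in enumerate(canon):
        others = set().union(*(canon[m] for m in range(spec.n_classes) if m != k))
        discriminative.append(sorted(pairs - others))
    labels = np.repeat(np.arange(spec.n_classes), spec.frames_per_class)
    truth = GroundTruth(
        labels=labels,
        planted_pairs=[sorted(c) for c in canon],
        discriminative_pairs=discriminative,
    )
    return refs, truth


def sample_ensemble(reference: ConformationalEnsemble, n_frames: int, sigma: float,
                    seed: int = 0) -> ConformationalEnsemble:
    """Draw frames as reference + i.i.d. Gaussian displacements (sigma per coordinate)."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    base = reference.coords[0]
    if sigma > 0:
        coords = base[None] + rng.normal(scale=sigma, size=(n_frames, *base.shape))
    else:
        coords = np.repeat(base[None], n_frames, axis=0)
    return ConformationalEnsemble(
        reference.topology, np.asarray(coords, dtype=float),
        [(f"sample-seed{seed}", i) for i in range(n_frames)],
    )


def generate_class_ensembles(
    spec: SyntheticSpec,
) -> tuple[list[ConformationalEnsemble], GroundTruth]:
    """Full benchmark: per-class noisy ensembles at the spec's study conditions."""
    refs, truth = generate_reference_structures(spec)
    ensembles = [
        sample_ensemble(ref, spec.frames_per_class, spec.noise_sigma,
                        seed=spec.seed + 1000 + k)
        for k, ref in enumerate(refs)
    ]
    return ensembles, truth


# ---------------------------------------------------------------------------
# toy ligand-receptor complex for the energetics stage

def generate_ligand_system(
    seed: int = 0,
    n_receptor: int = 30,
    n_ligand: int = 6,
    n_frames: int = 1,
    noise_sigma: float = 0.05,
    neutral_ligand: bool = False,
    charge_scale: float = 1.0,
) -> tuple[Topology, ConformationalEnsemble, dict[str, np.ndarray]]:
    """Coarse-grained complex with per-atom charge/LJ/Born parameters.

    The receptor is a folded bead chain (one bead per residue); the ligand is a
    compact cluster of beads docked against the receptor surface, including one
    salt-bridge partner (+0.8 e ligand bead facing a -0.8 e receptor bead) so
    electrostatics, LJ and GB terms are all O(1-100) kcal/mol.  Returns the
    complex topology, an ensemble, and the complex/receptor/ligand atom index
    sets used by the single-trajectory energy bookkeeping.
    """
    if not (20 <= n_receptor <= 40) or not (5 <= n_ligand <= 10):
        raise ValueError("receptor must have 20-40 beads and ligand 5-10 beads")
    rng = np.random.default_rng(seed)
    rec_coords = _build_reference(n_receptor, set(), rng)

    # dock the ligand against the chain midpoint, perpendicular to the local
    # tangent so the cluster sits off the chain rather than along it
    mid = n_receptor // 2
    anchor = rec_coords[mid]
    tangent = rec_coords[mid + 1] - rec_coords[mid - 1]
    tangent /= max(np.linalg.norm(tangent), 1e-9)
    outward = rng.normal(size=3)
    outward -= outward @ tangent * tangent
    outward /= max(np.linalg.norm(outward), 1e-9)
    lig_center = anchor + outward * 5.5
    lig_coords = lig_center + rng.normal(scale=1.2, size=(n_ligand, 3))
    # salt-bridge bead: as close to the anchor as the LJ wall allows
    salt = anchor + outward * 4.0
    for _ in range(100):
        if np.linalg.norm(rec_coords - salt, axis=1).min() >= 3.95:
            break
        salt = salt + outward * 0.1
    lig_coords[0] = salt

    # relax the remaining beads (salt bead stays put): outside the LJ wall of
    # the receptor, and >= 3.0 A from each other -- near-coincident beads put
    # intra-ligand LJ at ~1e10 kcal/mol, which cancels in the single-trajectory
    # deltas only up to float cancellation
    for _ in range(500):
        moved = False
        d = np.linalg.norm(lig_coords[:, None] - rec_coords[None], axis=2)
        bad = d.min(axis=1) < 3.95
        bad[0] = False
        if bad.any():
            lig_coords[bad] += outward * 0.3
            moved = True
        d = np.linalg.norm(lig_coords[:, None] - lig_coords[None], axis=2)
        np.fill_diagonal(d, np.inf)
        i, j = np.unravel_index(d.argmin(), d.shape)
        if d[i, j] < 3.0:
            mover = j if i == 0 else i
            other = i if i == 0 else j
            axis = lig_coords[mover] - lig_coords[other]
            norm = np.linalg.norm(axis)
            axis = axis / norm if norm > 1e-9 else rng.normal(size=3)
            lig_coords[mover] += 0.5 * axis
            moved = True
        if not moved:
            break

    coords = np.vstack([rec_coords, lig_coords])
    n_total = n_receptor + n_ligand

    charge = np.zeros(n_total)
    charge[:n_receptor] = rng.uniform(-0.3, 0.3, n_receptor)
    charge[n_receptor:] = rng.uniform(-0.2, 0.2, n_ligand)
    # salt bridge: receptor anchor bead vs first ligand bead
    charge[n_receptor // 2] = -0.8
    charge[n_receptor] = 0.8
    if neutral_ligand:
        charge[n_receptor:] = 0.0
    charge[n_receptor:] *= charge_scale

    topo = Topology(
        atom_names=["CA"] * n_receptor + [f"L{i + 1}" for i in range(n_ligand)],
        elements=["C"] * n_total,
        res_ids=np.concatenate([np.arange(1, n_receptor + 1),
                                np.full(n_ligand, n_receptor + 1)]),
        res_names=["GLY"] * n_receptor + ["LIG"] * n_ligand,
        chain_ids=["A"] * n_receptor + ["B"] * n_ligand,
        charge=charge,
        sigma=np.full(n_total, 3.5),
        epsilon=np.full(n_total, 0.6),
        born_radius=np.full(n_total, 1.8),
        mass=np.full(n_total, 12.0),
    )
    if n_frames == 1 or noise_sigma == 0:
        frames = np.repeat(coords[None], n_frames, axis=0)
    else:
        frames = coords[None] + rng.normal(scale=noise_sigma, size=(n_frames, n_total, 3))
    ens = ConformationalEnsemble(topo, frames)
    index_sets = {
        "complex": np.arange(n_total),
        "receptor": np.arange(n_receptor),
        "ligand": np.arange(n_receptor, n_total),
    }
    return topo, ens, index_sets
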
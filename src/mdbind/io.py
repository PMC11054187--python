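"""Topology, conformational-ensemble and annotation I/O.

The universal input of every analysis stage is a :class:`ConformationalEnsemble`:
a topology plus an ``F x A x 3`` coordinate array in Angstrom.  Multi-model PDB
(``MODEL``/``ENDMDL`` records) is the canonical on-disk ensemble format; a plain
whitespace-separated per-frame coordinate table is accepted as a dialect for
synthetic data.  Independent runs are merged into a single trajectory with
:func:`join_ensembles`, mirroring the common practice of concatenating several
independent MD runs before post-processing.

Residue indices are 1-based in all files and reports and 0-based internally;
the conversion is confined to this module.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Topology",
    "ConformationalEnsemble",
    "DomainAnnotation",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "read_coordinate_table",
    "write_coordinate_table",
    "join_ensembles",
    "read_domain_annotation",
    "read_atom_params",
]

_PDB_COORD_MAX = 9999.999
_PDB_COORD_MIN = -999.999


@dataclass
class Topology:
    """Ordered atom list with residue bookkeeping and optional parameters.

    Parameters are the per-atom force-field quantities the energetics stage
    needs: partial charge (e), Lennard-Jones sigma (A) and epsilon (kcal/mol),
    intrinsic Born radius (A) and mass (amu).  When present each array has
    exactly one entry per atom.
    """

    atom_names: list[str]
    elements: list[str]
    res_ids: np.ndarray          # 1-based residue sequence numbers, per atom
    res_names: list[str]         # per atom
    chain_ids: list[str]
    charge: np.ndarray | None = None
    sigma: np.ndarray | None = None
    epsilon: np.ndarray | None = None
    born_radius: np.ndarray | None = None
    mass: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        n = self.n_atoms
        if len(self.elements) != n or len(self.res_names) != n or len(self.chain_ids) != n:
            raise ValueError("per-atom fields must have one entry per atom")
        if np.any(np.diff(self.res_ids) < 0):
            raise ValueError("atom residue indices must be non-decreasing")
        for name in ("charge", "sigma", "epsilon", "born_radius", "mass"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (n,):
                    raise ValueError(f"parameter array {name!r} must have one entry per atom")
                setattr(self, name, arr)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids())

    def residue_ids(self) -> np.ndarray:
        """Distinct 1-based residue ids in order of first appearance."""
        _, idx = np.unique(self.res_ids, return_index=True)
        return self.res_ids[np.sort(idx)]

    def residue_index(self) -> np.ndarray:
        """0-based compact residue index per atom."""
        rid = self.residue_ids()
        lookup = {r: i for i, r in enumerate(rid)}
        return np.array([lookup[r] for r in self.res_ids], dtype=int)

    def residue_atom_indices(self) -> list[np.ndarray]:
        """Atom indices grouped by residue, in residue order."""
        ridx = self.residue_index()
        return [np.flatnonzero(ridx == i) for i in range(self.n_residues)]

    def residue_names(self) -> list[str]:
        """One name per residue, in residue order."""
        spans = self.residue_atom_indices()
        return [self.res_names[span[0]] for span in spans]

    def select(self, selection: str) -> np.ndarray:
        """Atom indices for a named selection.

        ``"calpha"`` -> CA atoms; ``"backbone"`` -> N/CA/C/O; ``"all"`` -> all;
        ``"heavy"`` -> non-hydrogen.
        """
        if selection == "all":
            return np.arange(self.n_atoms)
        if selection == "calpha":
            return np.array([i for i, a in enumerate(self.atom_names) if a == "CA"], dtype=int)
        if selection == "backbone":
            bb = {"N", "CA", "C", "O"}
            return np.array([i for i, a in enumerate(self.atom_names) if a in bb], dtype=int)
        if selection == "heavy":
            return np.array([i for i, e in enumerate(self.elements) if e.upper() != "H"], dtype=int)
        raise ValueError(f"unknown selection {selection!r}")

    def same_structure(self, other: "Topology") -> str | None:
        """None if topologies match, else a message naming the first mismatch."""
        if self.n_atoms != other.n_atoms:
            return f"atom count differs: {self.n_atoms} vs {other.n_atoms}"
        for i in range(self.n_atoms):
            if self.atom_names[i] != other.atom_names[i]:
                return f"atom {i}: name {self.atom_names[i]!r} vs {other.atom_names[i]!r}"
            if self.res_ids[i] != other.res_ids[i]:
                return f"atom {i}: residue id {self.res_ids[i]} vs {other.res_ids[i]}"
            if self.res_names[i] != other.res_names[i]:
                return f"atom {i}: residue name {self.res_names[i]!r} vs {other.res_names[i]!r}"
        return None


@dataclass
class ConformationalEnsemble:
    """Topology plus per-frame coordinates (Angstrom) with run provenance."""

    topology: Topology
    coords: np.ndarray                      # (F, A, 3)
    provenance: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (F, A, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("ensemble must contain at least one frame")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frames have {self.coords.shape[1]} atoms, topology has {self.topology.n_atoms}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if not self.provenance:
            self.provenance = [("run0", i) for i in range(self.n_frames)]
        if len(self.provenance) != self.n_frames:
            raise ValueError("provenance must have one entry per frame")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


@dataclass
class DomainAnnotation:
    """Named residue ranges (1-based, inclusive), e.g. helices and loops."""

    domains: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        seen: list[tuple[int, int]] = []
        for name, start, end in self.domains:
            if end < start:
                raise ValueError(f"domain {name!r}: end {end} < start {start}")
            for s, e in seen:
                if start <= e and s <= end:
                    raise ValueError(f"domain {name!r} overlaps a previous domain")
            seen.append((start, end))

    def validate_against(self, topology: Topology) -> None:
        rid = topology.residue_ids()
        lo, hi = int(rid.min()), int(rid.max())
        for name, start, end in self.domains:
            if start < lo or end > hi:
                raise ValueError(
                    f"domain {name!r} [{start}, {end}] outside topology residues [{lo}, {hi}]"
                )

    def domain_of(self, res_id: int) -> str | None:
        for name, start, end in self.domains:
            if start <= res_id <= end:
                return name
        return None


# ---------------------------------------------------------------------------
# multi-model PDB

def _model_atom_counts(text: str) -> list[int]:
    """ATOM/HETATM record count per MODEL block (whole file = one block if none)."""
    counts: list[int] = []
    current = 0
    in_model = False
    saw_model = False
    for line in text.splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            saw_model = True
            in_model = True
            current = 0
        elif rec == "ENDMDL":
            counts.append(current)
            in_model = False
        elif rec in ("ATOM", "HETATM"):
            current += 1
    if not saw_model:
        counts = [current]
    elif in_model:           # MODEL without ENDMDL
        counts.append(current)
    return counts


def read_multimodel_pdb(path) -> ConformationalEnsemble:
    """Read a (multi-model) PDB file into an ensemble.

    Frames are in file order; the atom order must be identical across models.
    A model with a deviating atom count is a hard error naming that model.
    """
    with open(path) as fh:
        text = fh.read()
    counts = _model_atom_counts(text)
    if not counts or counts[0] == 0:
        raise ValueError(f"{path}: no ATOM records found")
    for m, c in enumerate(counts, start=1):
        if c != counts[0]:
            raise ValueError(
                f"{path}: MODEL {m} has {c} atoms, expected {counts[0]} (as in MODEL 1)"
            )
    pdb = PDBFile.read(_io.StringIO(text))
    stack = pdb.get_structure(model=None)      # AtomArrayStack
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    first = stack[0]
    topo = Topology(
        atom_names=list(first.atom_name),
        elements=[e if e else "C" for e in first.element],
        res_ids=np.asarray(first.res_id, dtype=int),
        res_names=list(first.res_name),
        chain_ids=list(first.chain_id),
    )
    coords = np.asarray(stack.coord, dtype=float)
    return ConformationalEnsemble(topo, coords)


def write_multimodel_pdb(ens: ConformationalEnsemble, path) -> None:
    """Write an ensemble as a multi-model PDB (fixed-width, 3 decimals)."""
    if ens.n_frames < 1:
        raise ValueError("cannot write an empty ensemble")
    if ens.coords.max() > _PDB_COORD_MAX or ens.coords.min() < _PDB_COORD_MIN:
        raise ValueError("coordinates overflow the fixed-width PDB coordinate field")
    topo = ens.topology
    atoms = struc.AtomArray(topo.n_atoms)
    atoms.atom_name = np.array(topo.atom_names)
    atoms.element = np.array(topo.elements)
    atoms.res_id = topo.res_ids
    atoms.res_name = np.array(topo.res_names)
    atoms.chain_id = np.array(topo.chain_ids)
    atoms.hetero = np.zeros(topo.n_atoms, dtype=bool)
    stack = struc.from_template(atoms, ens.coords.astype(np.float32))
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# plain coordinate-table dialect (frame, atom, x, y, z)

def write_coordinate_table(ens: ConformationalEnsemble, path) -> None:
    with open(path, "w") as fh:
        fh.write("# frame atom x y z\n")
        for f in range(ens.n_frames):
            for a in range(ens.n_atoms):
                x, y, z = ens.coords[f, a]
                fh.write(f"{f} {a} {x:.6f} {y:.6f} {z:.6f}\n")


def read_coordinate_table(path, topology: Topology) -> ConformationalEnsemble:
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] != 5:
        raise ValueError("coordinate table must have 5 columns: frame atom x y z")
    frames = data[:, 0].astype(int)
    atoms = data[:, 1].astype(int)
    n_frames = frames.max() + 1
    n_atoms = topology.n_atoms
    coords = np.full((n_frames, n_atoms, 3), np.nan)
    coords[frames, atoms] = data[:, 2:5]
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinate table does not cover every (frame, atom) pair")
    return ConformationalEnsemble(topology, coords)


# ---------------------------------------------------------------------------

def join_ensembles(ensembles: list[ConformationalEnsemble]) -> ConformationalEnsemble:
    """Concatenate independent runs into a single merged trajectory.

    Topologies must match atom-for-atom; provenance keeps each frame's
    originating run id and within-run frame index.
    """
    if not ensembles:
        raise ValueError("no ensembles to join")
    ref = ensembles[0]
    provenance: list[tuple[str, int]] = []
    for k, ens in enumerate(ensembles):
        msg = ref.topology.same_structure(ens.topology)
        if msg is not None:
            raise ValueError(f"topology mismatch between ensemble 0 and {k}: {msg}")
        prov = ens.provenance
        # disambiguate run ids that repeat across inputs
        provenance.extend((f"{rid}" if len(ensembles) == 1 else f"run{k}:{rid}", fi)
                          for rid, fi in prov)
    coords = np.concatenate([e.coords for e in ensembles], axis=0)
    return ConformationalEnsemble(ref.topology, coords, provenance)


def read_domain_annotation(path, topology: Topology | None = None) -> DomainAnnotation:
    """Read a 3-column TSV (name, first residue, last residue; 1-based)."""
    domains: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"bad annotation line: {line!r}")
            domains.append((parts[0], int(parts[1]), int(parts[2])))
    ann = DomainAnnotation(domains)
    if topology is not None:
        ann.validate_against(topology)
    return ann


def read_atom_params(path, topology: Topology) -> Topology:
    """Attach per-atom parameters from a 7-column TSV keyed by atom serial.

    Columns: serial (1-based), charge, sigma, epsilon, born_radius, mass,
    residue, name -- the trailing residue/name columns are a readability
    check, not a join key.
    """
    n = topology.n_atoms
    charge = np.zeros(n)
    sigma = np.zeros(n)
    epsilon = np.zeros(n)
    born = np.zeros(n)
    mass = np.zeros(n)
    seen = np.zeros(n, dtype=bool)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            serial = int(parts[0]) - 1
            if not 0 <= serial < n:
                raise ValueError(f"atom serial {serial + 1} outside topology")
            charge[serial], sigma[serial], epsilon[serial], born[serial], mass[serial] = (
                float(parts[1]), float(parts[2]), float(parts[3]), float(parts[4]),
                float(parts[5]),
            )
            seen[serial] = True
    if not seen.all():
        missing = int(np.flatnonzero(~seen)[0]) + 1
        raise ValueError(f"parameter table missing atom serial {missing}")
    topology.charge = charge
    topology.sigma = sigma
    topology.epsilon = epsilon
    topology.born_radius = born
    topology.mass = mass
    return topology
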
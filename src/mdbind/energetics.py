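"""MM-GBSA-style binding free-energy bookkeeping and decomposition.

Binding free energy follows the end-state convention

    dG_bind = dH - T dS,        dH = dE_ele + dE_vdW + dG_gb + dG_surf,

with dG_pol = dE_ele + dG_gb the polar and dG_hydro = dE_vdW + dG_surf the
hydrophobic half.  Terms are evaluated in the single-trajectory approximation:
receptor and ligand coordinates are extracted from each complex frame, so all
intra-molecular molecular-mechanics terms cancel identically and dE_ele/dE_vdW
reduce to receptor-ligand cross sums.

The polar solvation term uses the pairwise Still-form generalized Born model
with user-supplied effective Born radii,

    G_gb = -(k_e/2)(1/eps_in - 1/eps_solv) sum_ij q_i q_j / f_gb,
    f_gb = sqrt(r^2 + a_i a_j exp(-r^2 / (4 a_i a_j))),

including self terms (f_gb = a_i at r = 0), which preserves the Born-ion
limit and the pairwise decomposability the per-residue analysis needs.  The
nonpolar term is the surface-area model dG_surf = gamma * dSASA + beta with
gamma = 0.0072 kcal mol^-1 A^-2 and beta = 0.

The entropy term is pluggable: supplied externally (to reproduce published
table arithmetic) or computed as a Schlitter quasi-harmonic upper bound from
the mass-weighted coordinate covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ConformationalEnsemble, Topology
from .metrics import sasa as _sasa
from .pca import KB_KCAL, _superposed_coords

__all__ = [
    "COULOMB_CONSTANT",
    "GAMMA_DEFAULT",
    "BETA_DEFAULT",
    "ForceFieldParams",
    "EnergyComponents",
    "BindingFreeEnergy",
    "EntropyEstimate",
    "coulomb_energy",
    "lj_energy",
    "gb_energy",
    "nonpolar_energy",
    "snapshot_components",
    "ensemble_components",
    "components_from_means",
    "aggregate_binding_free_energy",
    "compare_systems",
    "per_residue_decomposition",
    "quasiharmonic_entropy",
    "dg_from_ic50",
]

COULOMB_CONSTANT = 332.0636     # kcal A mol^-1 e^-2
GAMMA_DEFAULT = 0.0072          # kcal mol^-1 A^-2
BETA_DEFAULT = 0.0              # kcal mol^-1
GAS_CONSTANT = KB_KCAL          # kcal mol^-1 K^-1

# SI constants for the quasi-harmonic entropy bound
_KB_SI = 1.380649e-23           # J/K
_HBAR_SI = 1.054571817e-34      # J s
_AMU_KG = 1.66053906660e-27
_A2_M2 = 1e-20
_NA = 6.02214076e23
_J_PER_KCAL = 4184.0


@dataclass
class ForceFieldParams:
    """Dielectrics and surface-term coefficients for the GB/SA bookkeeping."""

    eps_in: float = 1.0
    eps_solv: float = 78.5
    gamma: float = GAMMA_DEFAULT
    beta: float = BETA_DEFAULT
    probe: float = 1.4
    sasa_points: int = 960

    def __post_init__(self) -> None:
        if not self.eps_solv > self.eps_in >= 1.0:
            raise ValueError("require eps_solv > eps_in >= 1")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")


@dataclass
class EnergyComponents:
    """Per-frame interaction components (kcal/mol)."""

    dele: np.ndarray
    dvdw: np.ndarray
    dggb: np.ndarray
    dgsurf: np.ndarray

    def __post_init__(self) -> None:
        for name in ("dele", "dvdw", "dggb", "dgsurf"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), float)))

    @property
    def dgpol(self) -> np.ndarray:
        return self.dele + self.dggb

    @property
    def dghydro(self) -> np.ndarray:
        return self.dvdw + self.dgsurf

    @property
    def dh(self) -> np.ndarray:
        return self.dele + self.dvdw + self.dggb + self.dgsurf

    @property
    def n_frames(self) -> int:
        return self.dele.size


@dataclass
class BindingFreeEnergy:
    """Ensemble-averaged components, entropy term and total binding free energy."""

    mean: dict[str, float]
    std: dict[str, float]
    minus_t_ds: float
    entropy_method: str = "supplied"
    n_frames: int = 1
    dg_exp: float | None = None

    @property
    def dgbind(self) -> float:
        return (self.mean["dele"] + self.mean["dvdw"] + self.mean["dggb"]
                + self.mean["dgsurf"] + self.minus_t_ds)

    @property
    def dgpol(self) -> float:
        return self.mean["dele"] + self.mean["dggb"]

    @property
    def dghydro(self) -> float:
        return self.mean["dvdw"] + self.mean["dgsurf"]

    def as_table(self) -> pd.DataFrame:
        rows = [
            ("dEele", self.mean["dele"], self.std["dele"]),
            ("dEvdw", self.mean["dvdw"], self.std["dvdw"]),
            ("dGgb", self.mean["dggb"], self.std["dggb"]),
            ("dGsurf", self.mean["dgsurf"], self.std["dgsurf"]),
            ("dGpol", self.dgpol, float("nan")),
            ("-TdS", self.minus_t_ds, float("nan")),
            ("dGbind", self.dgbind, float("nan")),
        ]
        return pd.DataFrame(rows, columns=["term", "mean", "std"])


@dataclass
class EntropyEstimate:
    minus_t_ds: float              # kcal/mol
    entropy: float                 # kcal mol^-1 K^-1
    temperature: float
    method: str = "quasiharmonic-schlitter"


# ---------------------------------------------------------------------------
# elementary terms

def _pair_array(pairs) -> np.ndarray:
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    return pairs


def coulomb_energy(coords: np.ndarray, charges: np.ndarray, pairs,
                   eps_in: float = 1.0) -> float:
    """Sum of k_e q_i q_j / (eps_in r_ij) over the pair set; no cutoff."""
    pairs = _pair_array(pairs)
    if len(pairs) == 0:
        return 0.0
    charges = np.asarray(charges, float)
    r = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    qq = charges[pairs[:, 0]] * charges[pairs[:, 1]]
    if np.any((r == 0) & (qq != 0)):
        raise ValueError("coincident charged pair (r = 0)")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(qq == 0, 0.0, COULOMB_CONSTANT * qq / (eps_in * r))
    return float(terms.sum())


def lj_energy(coords: np.ndarray, sigma: np.ndarray, epsilon: np.ndarray,
              pairs) -> float:
    """12-6 Lennard-Jones over the pair set with Lorentz-Berthelot combining."""
    pairs = _pair_array(pairs)
    if len(pairs) == 0:
        return 0.0
    sigma = np.asarray(sigma, float)
    epsilon = np.asarray(epsilon, float)
    r = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    if np.any(r == 0):
        raise ValueError("coincident atom pair (r = 0) in LJ sum")
    sij = 0.5 * (sigma[pairs[:, 0]] + sigma[pairs[:, 1]])
    eij = np.sqrt(epsilon[pairs[:, 0]] * epsilon[pairs[:, 1]])
    sr6 = (sij / r) ** 6
    return float(np.sum(4.0 * eij * (sr6 ** 2 - sr6)))


def _gb_pair_matrix(coords: np.ndarray, charges: np.ndarray, radii: np.ndarray,
                    eps_in: float, eps_solv: float) -> np.ndarray:
    """Full (A, A) matrix of Still-form GB pair terms (i = j gives self terms)."""
    charged = charges != 0
    if np.any(charged & (np.asarray(radii, float) <= 0)):
        raise ValueError("charged atom with non-positive Born radius")
    diff = coords[:, None, :] - coords[None, :, :]
    r2 = np.sum(diff * diff, axis=2)
    aa = np.outer(radii, radii)
    fgb = np.sqrt(r2 + aa * np.exp(-r2 / (4.0 * np.maximum(aa, 1e-30))))
    prefactor = -(COULOMB_CONSTANT / 2.0) * (1.0 / eps_in - 1.0 / eps_solv)
    qq = np.outer(charges, charges)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(qq == 0, 0.0, prefactor * qq / fgb)
    return terms


def gb_energy(coords: np.ndarray, charges: np.ndarray, radii: np.ndarray,
              eps_in: float = 1.0, eps_solv: float = 78.5) -> float:
    """Pairwise Still-form generalized-Born polar solvation energy.

    Includes self terms; the double sum over ordered pairs is halved by the
    prefactor, so a single ion of charge q and radius a gives the Born formula
    -(k_e/2)(1/eps_in - 1/eps_solv) q^2 / a.
    """
    terms = _gb_pair_matrix(np.asarray(coords, float), np.asarray(charges, float),
                            np.asarray(radii, float), eps_in, eps_solv)
    return float(terms.sum())


def nonpolar_energy(delta_sasa: float, gamma: float = GAMMA_DEFAULT,
                    beta: float = BETA_DEFAULT) -> float:
    """Surface-area nonpolar solvation term gamma * dSASA + beta."""
    return gamma * delta_sasa + beta


# ---------------------------------------------------------------------------
# single-trajectory snapshot bookkeeping

def _intra_pairs(idx: np.ndarray) -> np.ndarray:
    i, j = np.triu_indices(len(idx), k=1)
    return np.column_stack([idx[i], idx[j]])


def _cross_pairs(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.column_stack([np.repeat(a, len(b)), np.tile(b, len(a))])


def snapshot_components(coords: np.ndarray, topology: Topology,
                        index_sets: dict[str, np.ndarray],
                        params: ForceFieldParams | None = None) -> EnergyComponents:
    """dX = X(complex) - X(receptor) - X(ligand) for one frame.

    Receptor and ligand coordinates are taken from the complex frame (the
    single-trajectory convention), so the gas-phase deltas reduce exactly to
    receptor-ligand cross terms.
    """
    params = params or ForceFieldParams()
    rec = np.asarray(index_sets["receptor"], int)
    lig = np.asarray(index_sets["ligand"], int)
    if np.intersect1d(rec, lig).size:
        raise ValueError("receptor and ligand index sets overlap")
    com = np.asarray(index_sets.get("complex", np.concatenate([rec, lig])), int)
    q, s, e, a = topology.charge, topology.sigma, topology.epsilon, topology.born_radius
    if q is None or s is None or e is None or a is None:
        raise ValueError("topology lacks per-atom parameters")

    def gas(idx_pairs) -> tuple[float, float]:
        return (coulomb_energy(coords, q, idx_pairs, params.eps_in),
                lj_energy(coords, s, e, idx_pairs))

    ele_c, vdw_c = gas(_intra_pairs(com))
    ele_r, vdw_r = gas(_intra_pairs(rec))
    ele_l, vdw_l = gas(_intra_pairs(lig))

    dggb = (gb_energy(coords[com], q[com], a[com], params.eps_in, params.eps_solv)
            - gb_energy(coords[rec], q[rec], a[rec], params.eps_in, params.eps_solv)
            - gb_energy(coords[lig], q[lig], a[lig], params.eps_in, params.eps_solv))

    sasa_c, _ = _sasa(coords, topology, params.probe, params.sasa_points, subset=com)
    sasa_r, _ = _sasa(coords, topology, params.probe, params.sasa_points, subset=rec)
    sasa_l, _ = _sasa(coords, topology, params.probe, params.sasa_points, subset=lig)
    dgsurf = nonpolar_energy(sasa_c - sasa_r - sasa_l, params.gamma, params.beta)

    return EnergyComponents(
        dele=np.array([ele_c - ele_r - ele_l]),
        dvdw=np.array([vdw_c - vdw_r - vdw_l]),
        dggb=np.array([dggb]),
        dgsurf=np.array([dgsurf]),
    )


def ensemble_components(ensemble: ConformationalEnsemble,
                        index_sets: dict[str, np.ndarray],
                        params: ForceFieldParams | None = None,
                        n_frames: int | None = None) -> EnergyComponents:
    """Per-frame components over (an evenly strided subset of) an ensemble."""
    total = ensemble.n_frames
    if n_frames is None or n_frames >= total:
        frame_ids = np.arange(total)
    else:
        frame_ids = np.linspace(0, total - 1, n_frames).round().astype(int)
    parts = [snapshot_components(ensemble.coords[f], ensemble.topology,
                                 index_sets, params) for f in frame_ids]
    return EnergyComponents(
        dele=np.concatenate([p.dele for p in parts]),
        dvdw=np.concatenate([p.dvdw for p in parts]),
        dggb=np.concatenate([p.dggb for p in parts]),
        dgsurf=np.concatenate([p.dgsurf for p in parts]),
    )


def components_from_means(dele: float, dvdw: float, dggb: float,
                          dgsurf: float) -> EnergyComponents:
    """Single-frame components holding published (or otherwise external) means."""
    return EnergyComponents(np.array([dele]), np.array([dvdw]),
                            np.array([dggb]), np.array([dgsurf]))


def aggregate_binding_free_energy(components: EnergyComponents, minus_t_ds: float,
                                  entropy_method: str = "supplied",
                                  dg_exp: float | None = None) -> BindingFreeEnergy:
    """Means and standard deviations per component; dG_bind = dH-bar - T dS."""
    mean = {k: float(getattr(components, k).mean())
            for k in ("dele", "dvdw", "dggb", "dgsurf")}
    if components.n_frames > 1:
        std = {k: float(getattr(components, k).std(ddof=1))
               for k in ("dele", "dvdw", "dggb", "dgsurf")}
    else:
        std = {k: 0.0 for k in ("dele", "dvdw", "dggb", "dgsurf")}
    return BindingFreeEnergy(mean=mean, std=std, minus_t_ds=float(minus_t_ds),
                             entropy_method=entropy_method,
                             n_frames=components.n_frames, dg_exp=dg_exp)


def compare_systems(a: BindingFreeEnergy, b: BindingFreeEnergy) -> dict[str, float]:
    """Component-wise deltas (B - A) plus the favorable-force sum delta.

    A favorable component that becomes more negative in B shows up as a
    negative delta; its "strengthening" as usually reported is the magnitude
    of that delta.
    """
    delta = {k: b.mean[k] - a.mean[k] for k in ("dele", "dvdw", "dggb", "dgsurf")}
    delta["minus_t_ds"] = b.minus_t_ds - a.minus_t_ds
    delta["dgpol"] = b.dgpol - a.dgpol
    delta["dgbind"] = b.dgbind - a.dgbind
    delta["favorable_sum"] = delta["dvdw"] + delta["dgsurf"]
    return delta


# ---------------------------------------------------------------------------
# per-residue decomposition

def per_residue_decomposition(ensemble: ConformationalEnsemble,
                              index_sets: dict[str, np.ndarray],
                              params: ForceFieldParams | None = None,
                              key_threshold: float = 0.8,
                              n_frames: int | None = None) -> pd.DataFrame:
    """Inhibitor-residue interaction energies, averaged over frames.

    Each receptor residue receives its full Coulomb and LJ cross terms with
    the ligand, half of its pairwise GB cross terms (the other half belongs to
    the ligand), and gamma times its atoms' SASA change on binding.  A residue
    is flagged ``key`` when its total is at or below ``-key_threshold``
    kcal/mol (an interaction "stronger than" the threshold, favorable).
    """
    params = params or ForceFieldParams()
    topo = ensemble.topology
    rec = np.asarray(index_sets["receptor"], int)
    lig = np.asarray(index_sets["ligand"], int)
    com = np.asarray(index_sets.get("complex", np.concatenate([rec, lig])), int)
    q, s, e, a = topo.charge, topo.sigma, topo.epsilon, topo.born_radius
    ridx = topo.residue_index()
    res_ids = topo.residue_ids()
    res_names = topo.residue_names()
    rec_residues = sorted(set(int(ridx[i]) for i in rec))

    total = ensemble.n_frames
    if n_frames is None or n_frames >= total:
        frame_ids = np.arange(total)
    else:
        frame_ids = np.linspace(0, total - 1, n_frames).round().astype(int)

    acc = {r: np.zeros(4) for r in rec_residues}     # ele, vdw, gb, surf
    for f in frame_ids:
        coords = ensemble.coords[f]
        gb_terms = _gb_pair_matrix(coords[com], q[com], a[com],
                                   params.eps_in, params.eps_solv)
        pos = {atom: k for k, atom in enumerate(com)}
        _, per_atom_c = _sasa(coords, topo, params.probe, params.sasa_points, subset=com)
        _, per_atom_r = _sasa(coords, topo, params.probe, params.sasa_points, subset=rec)
        sasa_c = dict(zip(com, per_atom_c))
        sasa_r = dict(zip(rec, per_atom_r))
        for r in rec_residues:
            atoms = np.array([i for i in rec if ridx[i] == r], dtype=int)
            pairs = _cross_pairs(atoms, lig)
            ele = coulomb_energy(coords, q, pairs, params.eps_in)
            vdw = lj_energy(coords, s, e, pairs)
            # ordered-pair matrix: [i, j] alone is already half the (i, j)
            # interaction, i.e. the residue's half-share
            gb = sum(gb_terms[pos[i], pos[j]] for i in atoms for j in lig)
            surf = params.gamma * sum(sasa_c[i] - sasa_r[i] for i in atoms)
            acc[r] += np.array([ele, vdw, gb, surf])
    nf = len(frame_ids)
    rows = []
    for r in rec_residues:
        ele, vdw, gb, surf = acc[r] / nf
        tot = ele + vdw + gb + surf
        rows.append({
            "res_id": int(res_ids[r]), "res_name": res_names[r],
            "ele": ele, "vdw": vdw, "gb": gb, "surf": surf,
            "total": tot, "key": bool(tot <= -key_threshold),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# entropy and experiment

def quasiharmonic_entropy(ensemble: ConformationalEnsemble,
                          selection: str = "all", temperature: float = 300.0,
                          superpose: bool = True) -> EntropyEstimate:
    """Schlitter quasi-harmonic upper bound on configurational entropy.

    S <= (k_B/2) ln det(1 + (k_B T e^2 / hbar^2) M^(1/2) C M^(1/2)), with C the
    coordinate covariance (population-normalized) of the selected atoms after
    optional superposition.  Returns -T*S in kcal/mol (non-positive).
    """
    if ensemble.n_frames < 2:
        raise ValueError("entropy estimate needs at least 2 frames")
    idx = ensemble.topology.select(selection)
    if superpose and len(idx) >= 3:
        coords, _ = _superposed_coords(ensemble, selection, True)
    else:
        coords = ensemble.coords[:, idx]
    masses = (ensemble.topology.mass[idx] if ensemble.topology.mass is not None
              else np.full(len(idx), 12.0))
    x = coords.reshape(ensemble.n_frames, -1) * np.sqrt(_A2_M2)
    m = np.repeat(masses, 3) * _AMU_KG
    xc = x - x.mean(axis=0)
    cov = (xc.T @ xc) / x.shape[0]
    sigma = np.sqrt(m)[:, None] * cov * np.sqrt(m)[None, :]
    evals = np.clip(np.linalg.eigvalsh(sigma), 0.0, None)
    alpha = _KB_SI * temperature * np.e ** 2 / _HBAR_SI ** 2
    s_per_molecule = 0.5 * _KB_SI * np.sum(np.log1p(alpha * evals))
    s_kcal = s_per_molecule * _NA / _J_PER_KCAL      # kcal mol^-1 K^-1
    return EntropyEstimate(minus_t_ds=-temperature * s_kcal, entropy=s_kcal,
                           temperature=temperature)


def dg_from_ic50(ic50_molar: float, temperature: float = 300.0) -> float:
    """Experimental binding free energy from an IC50 (mol/L).

    Treating the IC50 as a dissociation constant, dG = RT ln(IC50), which is
    negative for sub-molar affinities (10 nM at 300 K gives -10.98 kcal/mol).
    """
    if ic50_molar <= 0:
        raise ValueError("IC50 must be positive")
    return float(GAS_CONSTANT * temperature * np.log(ic50_molar))
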
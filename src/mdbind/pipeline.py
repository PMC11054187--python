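"""End-to-end pipeline: simulate -> featurize -> train -> attribute, plus
metrics, PCA/FEL and GBSA stages, driven by one config and one seed.

Every stage writes plain-text artifacts (PDB, CSV/TSV, JSON, NPY for image
stacks) into the output directory and registers them in ``manifest.json``
together with checksums, seeds and the effective configuration, so a rerun
with the same config reproduces the run and ``resume=True`` skips completed
stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cnn as _cnn
from . import contacts as _contacts
from . import energetics as _energetics
from . import metrics as _metrics
from . import pca as _pca
from . import synthetic as _synthetic
from .io import (ConformationalEnsemble, join_ensembles, read_domain_annotation,
                 read_multimodel_pdb, write_multimodel_pdb)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger("mdbind.pipeline")

STAGE_ORDER = ["simulate", "featurize", "train", "attribute",
               "metrics", "pca", "fel", "gbsa", "report"]


@dataclass
class PipelineConfig:
    out_dir: str = "mdbind_run"
    stages: list[str] = field(default_factory=lambda: list(STAGE_ORDER))
    seed: int = 0
    # synthetic study conditions
    n_residues: int = 40
    frames_per_class: int = 300
    noise_sigma: float = 0.3
    # featurization / training
    cutoff: float = 4.5
    atom_rule: str = "calpha"
    split_fraction: float = 0.8
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 1e-3
    early_stop_accuracy: float | None = 0.99
    # landscapes
    bins: int = 60
    temperature: float = 300.0
    basin_threshold: float = 0.5
    # energetics
    gamma: float = _energetics.GAMMA_DEFAULT
    beta: float = _energetics.BETA_DEFAULT
    eps_in: float = 1.0
    eps_solv: float = 78.5
    gbsa_frames: int = 20
    resume: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split fraction must be in (0, 1)")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Run:
    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.out = Path(cfg.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        if cfg.resume and self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())
        else:
            self.manifest = {"config": asdict(cfg), "stages": {}}

    def stage_done(self, stage: str) -> bool:
        entry = self.manifest["stages"].get(stage)
        if not entry:
            return False
        return all((self.out / f).exists() for f in entry["files"])

    def record(self, stage: str, files: list[Path], elapsed: float) -> None:
        rel = [str(f.relative_to(self.out)) for f in files]
        self.manifest["stages"][stage] = {
            "files": rel,
            "sha256": {r: _sha256(self.out / r) for r in rel},
            "seconds": round(elapsed, 3),
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2))

    def require(self, stage: str, *files: str) -> None:
        for f in files:
            if not (self.out / f).exists():
                raise FileNotFoundError(
                    f"stage {stage!r} needs missing upstream output {f!r}; "
                    "run the producing stage first"
                )


def _load_class_ensembles(run: _Run) -> tuple[list[ConformationalEnsemble], dict]:
    truth = json.loads((run.out / "truth.json").read_text())
    return [read_multimodel_pdb(run.out / f"class_{k}.pdb")
            for k in range(truth["n_classes"])], truth


# --------------------------------------------------------------------- stages

def _stage_simulate(run: _Run) -> list[Path]:
    cfg = run.cfg
    spec = _synthetic.default_benchmark_spec(
        cfg.n_residues, cfg.frames_per_class, cfg.noise_sigma, seed=cfg.seed)
    ensembles, truth = _synthetic.generate_class_ensembles(spec)
    files = []
    for k, ens in enumerate(ensembles):
        p = run.out / f"class_{k}.pdb"
        write_multimodel_pdb(ens, p)
        files.append(p)
    dom = run.out / "domains.tsv"
    with open(dom, "w") as fh:
        for name, a, b in spec.domains.domains:
            fh.write(f"{name}\t{a}\t{b}\n")
    files.append(dom)
    tj = run.out / "truth.json"
    tj.write_text(json.dumps({
        "n_classes": spec.n_classes,
        "labels": truth.labels.tolist(),
        "planted_pairs": [[list(p) for p in c] for c in truth.planted_pairs],
        "discriminative_pairs": [[list(p) for p in c]
                                 for c in truth.discriminative_pairs],
    }, indent=2))
    files.append(tj)
    return files


def _stage_featurize(run: _Run) -> list[Path]:
    run.require("featurize", "truth.json", "class_0.pdb")
    ensembles, truth = _load_class_ensembles(run)
    cfg = run.cfg
    stacks = [_contacts.contact_maps(e, cfg.cutoff, cfg.atom_rule) for e in ensembles]
    images = np.concatenate([s.maps for s in stacks]).astype(np.float64)
    labels = np.concatenate([np.full(s.maps.shape[0], k)
                             for k, s in enumerate(stacks)])
    np.save(run.out / "images.npy", images)
    np.save(run.out / "labels.npy", labels)
    return [run.out / "images.npy", run.out / "labels.npy"]


def _stage_train(run: _Run) -> list[Path]:
    run.require("train", "images.npy", "labels.npy")
    cfg = run.cfg
    images = np.load(run.out / "images.npy")
    labels = np.load(run.out / "labels.npy")
    dataset = _contacts.ImageDataset(images=images, labels=labels)
    _contacts.split_train_val(dataset, cfg.split_fraction, seed=cfg.seed)
    spec = _cnn.CNNSpec(n_input=images.shape[1], n_classes=len(np.unique(labels)),
                        epochs=cfg.epochs, batch_size=cfg.batch_size,
                        learning_rate=cfg.learning_rate, seed=cfg.seed)
    model = _cnn.build_model(spec)
    result = _cnn.train_classifier(model, dataset, seed=cfg.seed,
                                   early_stop_accuracy=cfg.early_stop_accuracy)
    hist = pd.DataFrame({
        "epoch": np.arange(1, result.epochs_run + 1),
        "train_loss": result.train_loss, "train_accuracy": result.train_accuracy,
        "val_loss": result.val_loss, "val_accuracy": result.val_accuracy,
    })
    hist.to_csv(run.out / "train_history.csv", index=False)
    pd.DataFrame(result.confusion).to_csv(run.out / "confusion.csv", index=False)
    np.savez(run.out / "model.npz",
             **model.params,
             spec_n_input=spec.n_input, spec_n_classes=spec.n_classes,
             spec_seed=spec.seed)
    log.info("final validation accuracy %.2f%% after %d epochs",
             result.accuracy, result.epochs_run)
    return [run.out / "train_history.csv", run.out / "confusion.csv",
            run.out / "model.npz"]


def _load_model(run: _Run) -> _cnn.ContactCNN:
    data = np.load(run.out / "model.npz")
    spec = _cnn.CNNSpec(n_input=int(data["spec_n_input"]),
                        n_classes=int(data["spec_n_classes"]),
                        seed=int(data["spec_seed"]))
    model = _cnn.build_model(spec)
    for k in model.params:
        model.params[k] = data[k]
    model.trained = True
    return model


def _stage_attribute(run: _Run) -> list[Path]:
    run.require("attribute", "model.npz", "truth.json", "domains.tsv")
    ensembles, truth = _load_class_ensembles(run)
    model = _load_model(run)
    annotation = read_domain_annotation(run.out / "domains.tsv")
    files = []
    ranking_rows = []
    for k, ens in enumerate(ensembles):
        rep_frame, rep_map = _contacts.most_populated_representative(
            ens, cutoff=run.cfg.cutoff, atom_rule=run.cfg.atom_rule)
        image = rep_map.astype(float)
        sal = _cnn.vanilla_gradient_saliency(model, image, target=k)
        sal = _cnn.mask_and_aggregate(sal, rep_map, annotation,
                                      ens.topology.residue_ids())
        p = run.out / f"saliency_class_{k}.tsv"
        sal.domain_table.to_csv(p, sep="\t", index=False)
        files.append(p)
        top = sal.domain_table.iloc[0]
        ranking_rows.append({"class": k, "representative_frame": rep_frame,
                             "top_domain_a": top.domain_a,
                             "top_domain_b": top.domain_b,
                             "attribution": top.attribution})
    rank = run.out / "domain_ranking.tsv"
    pd.DataFrame(ranking_rows).to_csv(rank, sep="\t", index=False)
    files.append(rank)
    return files


def _stage_metrics(run: _Run) -> list[Path]:
    run.require("metrics", "truth.json", "class_0.pdb")
    ensembles, _ = _load_class_ensembles(run)
    files = []
    for k, ens in enumerate(ensembles):
        summary = _metrics.rmsd_series(ens, ens.coords[0], selection="calpha")
        fluct = _metrics.rmsf(ens, selection="calpha")
        rg = np.array([_metrics.radius_of_gyration(ens.coords[f], ens.topology)
                       for f in range(ens.n_frames)])
        p = run.out / f"metrics_class_{k}.csv"
        pd.DataFrame({"frame": np.arange(ens.n_frames),
                      "rmsd": summary.values, "rg": rg}).to_csv(p, index=False)
        files.append(p)
        pr = run.out / f"rmsf_class_{k}.csv"
        pd.DataFrame({"residue": ens.topology.residue_ids(),
                      "rmsf": fluct}).to_csv(pr, index=False)
        files.append(pr)
    return files


def _stage_pca(run: _Run) -> list[Path]:
    run.require("pca", "truth.json", "class_0.pdb")
    ensembles, _ = _load_class_ensembles(run)
    merged = join_ensembles(ensembles)
    model = _pca.build_pca(merged)
    fractions, cum = _pca.variance_fractions(model, min(6, model.eigenvalues.size))
    proj = _pca.project(merged, model, k=2)
    pd.DataFrame({"mode": np.arange(1, len(fractions) + 1),
                  "eigenvalue": model.eigenvalues[:len(fractions)],
                  "fraction_pct": fractions}).to_csv(
        run.out / "eigenvalues.csv", index=False)
    pd.DataFrame({"frame": np.arange(proj.shape[0]),
                  "pc1": proj[:, 0], "pc2": proj[:, 1]}).to_csv(
        run.out / "projections.csv", index=False)
    disp = _pca.mode_displacements(model, 0)
    pd.DataFrame({"residue": merged.topology.residue_ids(),
                  "displacement": disp}).to_csv(
        run.out / "mode1_displacements.csv", index=False)
    return [run.out / "eigenvalues.csv", run.out / "projections.csv",
            run.out / "mode1_displacements.csv"]


def _stage_fel(run: _Run) -> list[Path]:
    run.require("fel", "projections.csv")
    proj = pd.read_csv(run.out / "projections.csv")[["pc1", "pc2"]].to_numpy()
    grid = _pca.free_energy_landscape(proj, bins=run.cfg.bins,
                                      temperature=run.cfg.temperature)
    basins = _pca.find_basins(grid, run.cfg.basin_threshold, projections=proj)
    np.savetxt(run.out / "fel.tsv", grid.free_energy, delimiter="\t", fmt="%.6f")
    (run.out / "basins.json").write_text(json.dumps({
        "n_basins": len(basins),
        "basins": [{"id": b.basin_id, "min_bin": list(b.min_bin),
                    "min_energy": b.min_energy,
                    "representative_frame": b.representative_frame,
                    "n_bins": len(b.member_bins)} for b in basins.basins],
    }, indent=2))
    return [run.out / "fel.tsv", run.out / "basins.json"]


def _stage_gbsa(run: _Run) -> list[Path]:
    cfg = run.cfg
    topo, ens, index_sets = _synthetic.generate_ligand_system(
        seed=cfg.seed, n_frames=cfg.gbsa_frames, noise_sigma=0.05)
    params = _energetics.ForceFieldParams(eps_in=cfg.eps_in, eps_solv=cfg.eps_solv,
                                          gamma=cfg.gamma, beta=cfg.beta)
    comp = _energetics.ensemble_components(ens, index_sets, params)
    entropy = _energetics.quasiharmonic_entropy(ens, temperature=cfg.temperature)
    energy = _energetics.aggregate_binding_free_energy(
        comp, entropy.minus_t_ds, entropy_method=entropy.method)
    energy.as_table().to_csv(run.out / "gbsa_summary.tsv", sep="\t", index=False)
    decomp = _energetics.per_residue_decomposition(ens, index_sets, params,
                                                   n_frames=min(5, cfg.gbsa_frames))
    decomp.to_csv(run.out / "gbsa_residues.tsv", sep="\t", index=False)
    return [run.out / "gbsa_summary.tsv", run.out / "gbsa_residues.tsv"]


def _stage_report(run: _Run) -> list[Path]:
    lines = ["# mdbind run report", ""]
    for name in ("confusion.csv", "domain_ranking.tsv", "gbsa_summary.tsv",
                 "eigenvalues.csv", "basins.json"):
        p = run.out / name
        if p.exists():
            lines.append(f"## {name}")
            lines.append("```")
            lines.append(p.read_text().strip())
            lines.append("```")
            lines.append("")
    p = run.out / "report.md"
    p.write_text("\n".join(lines))
    return [p]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "featurize": _stage_featurize,
    "train": _stage_train,
    "attribute": _stage_attribute,
    "metrics": _stage_metrics,
    "pca": _stage_pca,
    "fel": _stage_fel,
    "gbsa": _stage_gbsa,
    "report": _stage_report,
}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages in dependency order; return the manifest."""
    run = _Run(cfg)
    for stage in STAGE_ORDER:
        if stage not in cfg.stages:
            continue
        if cfg.resume and run.stage_done(stage):
            log.info("stage %s: up to date, skipped", stage)
            continue
        log.info("stage %s: starting (seed %d)", stage, cfg.seed)
        t0 = time.time()
        files = _STAGE_FUNCS[stage](run)
        run.record(stage, files, time.time() - t0)
        log.info("stage %s: done in %.1fs", stage, time.time() - t0)
    return run.manifest
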
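"""End-to-end orchestration: simulate, train, analyse, report.

One seeded run generates feature norms and visual embeddings, trains the
attractor network, assembles the ordered stage trajectory (visual layers
followed by semantic time-ticks), computes stage RDMs and feature
dynamics, builds a synthetic brain with planted stage geometry, and runs
the ROI, searchlight and gradient analyses.  The report is a plain
serialisable summary; a run is reproducible from config plus seed alone.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import attractor, featstats, rsa, syndata
from .gradient import fit_stage_curve, region_stage_interaction
from .syndata import RegionSpec, StageRepresentation

__all__ = [
    "RunConfig",
    "RunReport",
    "validate_config",
    "load_config",
    "run_pipeline",
    "build_stage_trajectory",
]


@dataclass
class RunConfig:
    """All knobs of a pipeline run; defaults are the study conditions."""

    seed: int = 0
    # norms
    n_concepts: int = 60
    n_categories: int = 6
    features_per_concept: int = 14
    # embeddings / visual trajectory
    n_dims: int = 20
    visual_coupling: float = 0.8
    noise_sd: float = 0.5
    n_layers: int = 7
    mixing_decay: float = 0.7
    # attractor network
    c: float = 0.25
    n_ticks: int = 20
    lr: float = 0.01
    momentum: float = 0.9
    max_epochs: int = 2000
    criterion_frac: float = 0.95
    criterion_level: float = 0.70
    t_err: int = 2
    # synthetic brain: (region name, generative stage id) pairs, posterior
    # to anterior; defaults plant a mid visual layer, an early semantic
    # tick and a late semantic tick
    regions: tuple = (
        ("EVC", "visual_layer1"),
        ("pVTC", "semantic_tick3"),
        ("PrC", "semantic_tick20"),
    )
    n_subjects: int = 12
    snr: float = 2.0
    # rsa
    roi_n_perm: int = 1000
    searchlight: bool = True
    radius: float = 2.0
    fdr: float = 0.01
    group_n_perm: int = 2000
    smoothing_fwhm: float = 0.0
    # gradient
    gradient_n_perm: int = 2000
    knot_candidates: tuple = (3, 4, 5)

    def n_stages(self) -> int:
        return self.n_layers + self.n_ticks - 1


_RANGES = {
    "c": (0.0, 1.0, "(0, 1]"),
    "criterion_frac": (0.0, 1.0, "(0, 1]"),
    "criterion_level": (0.0, 1.0, "(0, 1)"),
    "visual_coupling": (-1e-12, 1.0, "[0, 1]"),
    "fdr": (0.0, 1.0, "(0, 1)"),
}


def validate_config(raw: dict | RunConfig | None = None) -> RunConfig:
    """Build a RunConfig from a raw mapping with aggregated validation.

    Unknown keys are rejected; every violated field is named in the error.
    """
    if raw is None:
        raw = {}
    if isinstance(raw, RunConfig):
        raw = dataclasses.asdict(raw)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    errors = []
    unknown = set(raw) - known
    if unknown:
        errors.append(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**{k: v for k, v in raw.items() if k in known})
    for name, (lo, hi, desc) in _RANGES.items():
        v = getattr(cfg, name)
        closed_low = desc.startswith("[")
        closed_high = desc.endswith("]")
        ok = (v >= lo if closed_low else v > lo) and (v <= hi if closed_high else v < hi)
        if not ok:
            errors.append(f"{name}={v} outside {desc}")
    for name in ("n_concepts", "n_categories", "features_per_concept", "n_dims",
                 "n_layers", "n_ticks", "n_subjects", "max_epochs"):
        if getattr(cfg, name) < 1:
            errors.append(f"{name} must be >= 1")
    if cfg.n_concepts < cfg.n_categories:
        errors.append("n_concepts must be >= n_categories")
    if cfg.n_ticks < 2:
        errors.append("n_ticks must be >= 2")
    if cfg.snr <= 0:
        errors.append("snr must be > 0")
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    for pname in ("roi_n_perm", "group_n_perm", "gradient_n_perm"):
        if getattr(cfg, pname) < 100:
            warnings.warn(
                f"{pname}={getattr(cfg, pname)} is below the recommended "
                "minimum of 100; p-values will be coarse",
                stacklevel=2,
            )
    return cfg


def load_config(path) -> RunConfig:
    """Read and validate a YAML run configuration."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    return validate_config(raw)


def build_stage_trajectory(
    net: attractor.AttractorNetwork,
    inputs: np.ndarray,
    visual_stages: list[StageRepresentation],
    items: list[str],
) -> list[StageRepresentation]:
    """Ordered full-model trajectory: visual layers, then semantic ticks 2..T.

    The first semantic tick is the random initialisation, identical across
    items, and is excluded; a run with L visual layers and T ticks yields
    L + (T - 1) stages.
    """
    traj = attractor.run_ticks(net, inputs)
    stages = list(visual_stages)
    for t in range(2, net.n_ticks + 1):
        stages.append(
            StageRepresentation(
                stage_id=f"semantic_tick{t}", items=list(items), matrix=traj.at_tick(t)
            )
        )
    return stages


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    config: RunConfig
    stage_ids: list[str]
    epochs_run: int
    converged: bool
    criterion_frac_final: float
    curves_sharedness: dict
    curves_type: dict
    fit_table: pd.DataFrame
    roi_best_stage: dict[str, int]
    noise_ceiling: dict[str, float]
    curve_shapes: dict[str, str]
    interaction_F: float
    interaction_p: float
    composite_modal_stage: dict[str, int] | None = None
    composite_assigned_frac: dict[str, float] | None = None
    stage_rdms: dict | None = None
    brain: syndata.SyntheticBrain | None = None

    def metrics(self) -> dict:
        """The scalar metrics of the run, JSON-ready."""
        out = {
            "n_stages": len(self.stage_ids),
            "epochs_run": self.epochs_run,
            "converged": self.converged,
            "criterion_frac_final": self.criterion_frac_final,
            "roi_best_stage": self.roi_best_stage,
            "noise_ceiling": self.noise_ceiling,
            "curve_shapes": self.curve_shapes,
            "interaction_F": self.interaction_F,
            "interaction_p": self.interaction_p,
        }
        if self.composite_modal_stage is not None:
            out["composite_modal_stage"] = self.composite_modal_stage
            out["composite_assigned_frac"] = self.composite_assigned_frac
        return out

    def save(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(
            json.dumps(
                {"config": dataclasses.asdict(self.config), "metrics": self.metrics()},
                indent=2,
                default=lambda o: list(o) if isinstance(o, tuple) else str(o),
            )
        )
        self.fit_table.to_csv(out_dir / "fit_table.tsv", sep="\t", index=False)
        pd.DataFrame(self.curves_sharedness).to_csv(out_dir / "curves_sharedness.tsv", sep="\t")
        pd.DataFrame(self.curves_type).to_csv(out_dir / "curves_type.tsv", sep="\t")


def run_pipeline(config: RunConfig | dict | None = None) -> RunReport:
    """Execute the full simulate -> train -> analyse pipeline."""
    cfg = validate_config(config)
    seed = np.random.SeedSequence(cfg.seed)

    # --- simulate inputs
    norms = syndata.gen_feature_norms(
        n_concepts=cfg.n_concepts,
        n_categories=cfg.n_categories,
        features_per_concept=cfg.features_per_concept,
        seed=seed,
    )
    emb = syndata.gen_visual_embeddings(
        norms,
        n_dims=cfg.n_dims,
        visual_coupling=cfg.visual_coupling,
        noise_sd=cfg.noise_sd,
        seed=seed,
    )
    inputs, _ = syndata.svd_reduce(emb, cfg.n_dims)
    visual_stages = syndata.gen_visual_stage_trajectory(
        inputs, n_layers=cfg.n_layers, mixing_decay=cfg.mixing_decay,
        seed=seed, items=norms.concept_ids,
    )

    # --- train the attractor network
    net0 = attractor.init_network(
        input_dim=inputs.shape[1],
        semantic_dim=norms.matrix.shape[1],
        c=cfg.c,
        n_ticks=cfg.n_ticks,
        seed=syndata.substream(seed, "network").integers(2**31),
    )
    net, epochs_run, hist = attractor.train_bptt(
        net0,
        inputs,
        norms.matrix,
        lr=cfg.lr,
        max_epochs=cfg.max_epochs,
        criterion_frac=cfg.criterion_frac,
        criterion_level=cfg.criterion_level,
        momentum=cfg.momentum,
        t_err=cfg.t_err,
    )
    if not hist.converged:
        warnings.warn(
            f"training criterion not reached within {cfg.max_epochs} epochs "
            f"(final fraction {hist.criterion_frac[-1]:.3f})",
            stacklevel=2,
        )

    # --- stage trajectory and RDMs
    stages = build_stage_trajectory(net, inputs, visual_stages, norms.concept_ids)
    stage_ids = [s.stage_id for s in stages]
    rdms = {s.stage_id: rsa.compute_rdm(s) for s in stages}

    # --- feature dynamics
    traj = attractor.run_ticks(net, inputs)
    classes = featstats.classify_features(norms)
    curves_sh = featstats.activation_curves(traj, norms, classes, "sharedness3")
    curves_ty = featstats.activation_curves(traj, norms, classes, "feature_type")

    # --- synthetic brain and ROI analysis
    specs = [RegionSpec(name, sid, snr=cfg.snr) for name, sid in cfg.regions]
    brain = syndata.gen_synthetic_brain(
        stages, specs, n_subjects=cfg.n_subjects, snr=cfg.snr, seed=seed,
    )
    rows = []
    subject_rdms: dict[str, list[rsa.RDM]] = {name: [] for name, _ in cfg.regions}
    for name, _ in cfg.regions:
        vox = brain.region_voxels(name)
        for s in range(cfg.n_subjects):
            neural = rsa.compute_rdm_from_patterns(
                brain.patterns[s][:, vox], items=norms.concept_ids
            )
            subject_rdms[name].append(neural)
            for k, sid in enumerate(stage_ids, start=1):
                rows.append(
                    {
                        "subject": f"sub{s:02d}",
                        "region": name,
                        "stage_index": k,
                        "stage_id": sid,
                        "rho": rsa.compare_rdms(neural, rdms[sid]),
                    }
                )
    fit_table = pd.DataFrame(rows)
    mean_rho = fit_table.groupby(["region", "stage_index"])["rho"].mean()
    roi_best = {
        name: int(mean_rho.loc[name].idxmax()) for name, _ in cfg.regions
    }
    ceilings = {
        name: rsa.noise_ceiling_lower(subject_rdms[name]) for name, _ in cfg.regions
    }

    # --- stage-gradient analysis
    shapes = {}
    for name, _ in cfg.regions:
        curve = fit_stage_curve(fit_table, name, knot_candidates=tuple(cfg.knot_candidates))
        shapes[name] = curve.shape
    inter = region_stage_interaction(
        fit_table,
        n_perm=cfg.gradient_n_perm,
        seed=syndata.substream(seed, "interaction_perm").integers(2**31),
    )

    # --- searchlight, group inference, composite map
    composite_modal = None
    assigned_frac = None
    if cfg.searchlight:
        per_stage = {sid: [] for sid in stage_ids}
        for s in range(cfg.n_subjects):
            maps = rsa.searchlight_map(
                brain, None, radius=cfg.radius, subject=s, model_rdms=rdms
            )
            for sid in stage_ids:
                per_stage[sid].append(maps[sid])
        masks, means = {}, {}
        g_seed = syndata.substream(seed, "group_perm").integers(2**31)
        for sid in stage_ids:
            g = rsa.group_inference(
                np.stack(per_stage[sid]),
                alpha_fdr=cfg.fdr,
                n_perm=cfg.group_n_perm,
                smoothing_fwhm=cfg.smoothing_fwhm,
                grid_shape=brain.grid_shape,
                seed=g_seed,
            )
            masks[sid] = g.mask
            means[sid] = g.mean_z
        comp = rsa.composite_best_stage_map(means, masks)
        composite_modal, assigned_frac = {}, {}
        for name, _ in cfg.regions:
            vox = brain.region_voxels(name)
            assigned = comp[vox]
            assigned = assigned[assigned > 0]
            assigned_frac[name] = float(len(assigned) / len(vox))
            composite_modal[name] = (
                int(np.bincount(assigned).argmax()) if len(assigned) else 0
            )

    return RunReport(
        config=cfg,
        stage_ids=stage_ids,
        epochs_run=epochs_run,
        converged=hist.converged,
        criterion_frac_final=float(hist.criterion_frac[-1]),
        curves_sharedness={g: v.tolist() for g, v in curves_sh.curves.items()},
        curves_type={g: v.tolist() for g, v in curves_ty.curves.items()},
        fit_table=fit_table,
        roi_best_stage=roi_best,
        noise_ceiling=ceilings,
        curve_shapes=shapes,
        interaction_F=inter.F,
        interaction_p=inter.p,
        composite_modal_stage=composite_modal,
        composite_assigned_frac=assigned_frac,
        stage_rdms=rdms,
        brain=brain,
    )
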
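"""End-to-end experiment orchestration on synthetic or loaded data.

``run_experiment`` wires the stages together in dependency order:
simulate -> preprocess -> per-fold model training (PCA baseline, plain
autoencoder, fixed-effects, random-effects) -> separability evaluation
-> latent-fusion classification -> counterfactual projection ->
genomap rendering.  Every run writes deterministic CSV artifacts plus
a JSON manifest with config snapshot, seeds, per-stage timings and
sha256 checksums, so identical configs produce identical outputs.

``suggest_loss_weights`` implements the loss-balancing heuristic: run
short probes with all weights at 1, measure the mean magnitude of each
loss term over the probe epochs, and rescale every non-reconstruction
term to the reconstruction term's magnitude (rounded to one
significant figure).
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.decomposition import PCA

from .counterfactual import build_projection_panel, projection_contrast
from .data_model import (CELLTYPE_KEY, BatchDesign, LatentSpace,
                         make_batch_design, make_cell_type_labels,
                         stratified_kfold)
from .evaluation import (classify_latent, fuse_latents, report_across_folds,
                         separability_metrics)
from .fe import FEConfig, FixedEffectsAutoencoder, PlainAutoencoder
from .genomap import fit_genomap_layout, genomap_montage
from .preprocessing import PreprocessConfig, fit_standardizer, preprocess
from .re import REConfig, RandomEffectsAutoencoder
from .synthetic import SimConfig, simulate

__all__ = ["PipelineConfig", "RunManifest", "run_experiment", "suggest_loss_weights"]

ALL_STAGES = ("simulate", "preprocess", "train_fe", "train_re", "evaluate",
              "project", "genomap", "classify")


@dataclass
class PipelineConfig:
    """Complete configuration of one experiment run."""

    outdir: str = "runs/run0"
    input_path: str | None = None  # load instead of simulate when given
    seed: int = 0
    n_folds: int = 5
    val_fraction: float = 0.1
    fec: bool = False  # enable the cell-type classifier head on the FE model
    sim: SimConfig = field(default_factory=SimConfig)
    prep: PreprocessConfig = field(default_factory=PreprocessConfig)
    fe: FEConfig = field(default_factory=FEConfig)
    re: REConfig = field(default_factory=REConfig)
    panel_cells: int = 300
    panel_cell_type: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        for key, sub in (("sim", SimConfig), ("prep", PreprocessConfig),
                         ("fe", FEConfig), ("re", REConfig)):
            if key in kwargs and isinstance(kwargs[key], dict):
                d = kwargs[key]
                for k in ("encoder_sizes", "adversary_hidden_sizes"):
                    if isinstance(d.get(k), list):
                        d[k] = tuple(d[k])
                kwargs[key] = sub(**d)
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(asdict(self), default=list)), fh,
                           sort_keys=True)


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    stages: dict = field(default_factory=dict)  # stage -> {seconds, outputs: {path: sha256}}

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.config, "version": self.version,
                       "seed": self.seed, "stages": self.stages}, fh, indent=2,
                      default=list)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _pca_latent(X, fold, dim, cell_ids, seed) -> LatentSpace:
    fit_idx = np.concatenate([fold.train_cells, fold.val_cells])
    pca = PCA(n_components=dim, random_state=seed).fit(X[fit_idx])
    return LatentSpace(pca.transform(X), cell_ids, source="PCA",
                       fold_index=fold.fold_index, seed=seed)


def run_experiment(config: PipelineConfig, stages=ALL_STAGES) -> RunManifest:
    """Run the requested stages in dependency order; returns the manifest."""
    from . import __version__

    stages = list(stages)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=json.loads(json.dumps(asdict(config), default=list)),
                           version=__version__, seed=config.seed)
    manifest.write(outdir / "manifest.json")
    config.to_yaml(outdir / "effective_config.yaml")

    ctx: dict = {}

    def record(stage, t0, outputs):
        manifest.stages[stage] = {
            "seconds": round(time.time() - t0, 3),
            "outputs": {str(p): _sha256(Path(p)) for p in outputs},
        }

    # ---- data ----------------------------------------------------------
    t0 = time.time()
    if config.input_path is not None:
        from .data_model import load_expression

        ctx["raw"] = load_expression(config.input_path)
        ctx["truth"] = None
    else:
        sim_cfg = SimConfig(**{**asdict(config.sim), "seed": config.seed})
        ctx["raw"], ctx["truth"] = simulate(sim_cfg)
    if "simulate" in stages:
        record("simulate", t0, [])

    t0 = time.time()
    ds = preprocess(ctx["raw"], config.prep)
    ctx["dataset"] = ds
    ctx["design"] = make_batch_design(ds)
    ctx["labels"] = (make_cell_type_labels(ds)
                     if CELLTYPE_KEY in ds.annotations.columns else None)
    ctx["folds"] = stratified_kfold(ds, k=config.n_folds,
                                    val_fraction=config.val_fraction, seed=config.seed)
    if "preprocess" in stages:
        record("preprocess", t0, [])

    needs_models = {"train_fe", "train_re", "evaluate", "project", "genomap",
                    "classify"} & set(stages)
    if not needs_models:
        manifest.write(outdir / "manifest.json")
        return manifest

    # ---- per-fold models ----------------------------------------------
    t0 = time.time()
    ctx["scalers"], ctx["X"] = [], []
    ctx["ae"], ctx["fe"], ctx["re"], ctx["pca"] = [], [], [], []
    fe_hist, re_hist = [], []
    for fold in ctx["folds"]:
        scaler = fit_standardizer(ds, fold.train_cells)
        X = scaler.transform(ds.counts)
        ctx["scalers"].append(scaler)
        ctx["X"].append(X)
        fe_kwargs = asdict(config.fe)
        fe_kwargs["seed"] = config.seed + fold.fold_index
        if config.fec and ctx["labels"] is not None and fe_kwargs["lambda_y"] == 0:
            fe_kwargs["lambda_y"] = 1.0
        fe = FixedEffectsAutoencoder(**fe_kwargs)
        fe.fit(X, design=ctx["design"],
               labels=ctx["labels"] if fe_kwargs["lambda_y"] > 0 else None,
               train_idx=fold.train_cells, val_idx=fold.val_cells)
        ctx["fe"].append(fe)
        fe_hist.append(fe.history_.assign(fold=fold.fold_index, model=fe.source_))

        ae_kwargs = {k: v for k, v in fe_kwargs.items()
                     if k in ("encoder_sizes", "latent_dim", "activation",
                              "lambda_recon_f", "learning_rate", "max_epochs",
                              "patience", "batch_size", "seed")}
        ae = PlainAutoencoder(**ae_kwargs)
        ae.fit(X, design=ctx["design"], train_idx=fold.train_cells,
               val_idx=fold.val_cells)
        ctx["ae"].append(ae)

        re_kwargs = asdict(config.re)
        re_kwargs["seed"] = config.seed + fold.fold_index
        rem = RandomEffectsAutoencoder(**re_kwargs)
        rem.fit(X, design=ctx["design"], train_idx=fold.train_cells,
                val_idx=fold.val_cells)
        ctx["re"].append(rem)
        re_hist.append(rem.history_.assign(fold=fold.fold_index, model="RE"))

        ctx["pca"].append(_pca_latent(X, fold, config.fe.latent_dim, ds.cell_ids,
                                      config.seed))
    outputs = []
    if {"train_fe", "train_re"} & set(stages):
        hist_path = outdir / "training_history.csv"
        pd.concat(fe_hist + re_hist, ignore_index=True).to_csv(hist_path, index=False)
        outputs.append(hist_path)
    record("train_fe", t0, outputs)
    manifest.stages["train_re"] = manifest.stages["train_fe"]

    def latents_for(source: str) -> list[LatentSpace]:
        out = []
        for f, fold in enumerate(ctx["folds"]):
            X = ctx["X"][f]
            if source == "PCA":
                out.append(ctx["pca"][f])
            elif source == "AE":
                out.append(LatentSpace(ctx["ae"][f].transform(X), ds.cell_ids,
                                       "AE", f, config.seed))
            elif source in ("FE", "FEC"):
                out.append(LatentSpace(ctx["fe"][f].transform(X), ds.cell_ids,
                                       ctx["fe"][f].source_, f, config.seed))
            elif source == "RE":
                out.append(LatentSpace(ctx["re"][f].transform(X, ctx["design"]),
                                       ds.cell_ids, "RE", f, config.seed))
        return out

    # ---- Experiment 1: separability ------------------------------------
    if "evaluate" in stages:
        t0 = time.time()
        rows = []
        for source in ("PCA", "AE", "FE", "RE"):
            for ls in latents_for(source):
                fold = ctx["folds"][ls.fold_index]
                emb = ls.embedding[fold.test_cells]
                for labeling, lab in (("batch", ds.batch_labels),
                                      ("cell_type", ds.cell_type_labels)):
                    if lab is None:
                        continue
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        m = separability_metrics(emb, lab[fold.test_cells])
                    for metric, value in m.items():
                        rows.append({"source": ls.source, "labeling": labeling,
                                     "fold": ls.fold_index, "metric": metric,
                                     "value": value})
        report = pd.DataFrame(rows)
        report_path = outdir / "separability.csv"
        report.to_csv(report_path, index=False)
        summary_rows = []
        for (source, labeling, metric), grp in report.groupby(
                ["source", "labeling", "metric"]):
            if len(grp) >= 2:
                agg = report_across_folds(grp["value"])
                summary_rows.append({"source": source, "labeling": labeling,
                                     "metric": metric, **agg})
        summary_path = outdir / "separability_summary.csv"
        pd.DataFrame(summary_rows).to_csv(summary_path, index=False)
        record("evaluate", t0, [report_path, summary_path])

    # ---- Experiment 2: classification ----------------------------------
    if "classify" in stages:
        t0 = time.time()
        targets = {}
        if ds.cell_type_labels is not None:
            targets["cell_type"] = ds.cell_type_labels
        targets["batch"] = ds.batch_labels
        frames = []
        fe_lat, re_lat, pca_lat = (latents_for("FE"), latents_for("RE"),
                                   latents_for("PCA"))
        fused = []
        for f, fold in enumerate(ctx["folds"]):
            fit_idx = np.concatenate([fold.train_cells, fold.val_cells])
            fused.append(fuse_latents(fe_lat[f], re_lat[f], fit_idx=fit_idx))
        for tname, tvec in targets.items():
            for name, lats in (("PCA", pca_lat), ("FE", fe_lat), ("fused", fused)):
                rep = classify_latent(lats, tvec, ctx["folds"], seed=config.seed)
                rep["target"] = tname
                rep["input"] = name
                frames.append(rep)
        cls_path = outdir / "classification.csv"
        pd.concat(frames, ignore_index=True).to_csv(cls_path, index=False)
        record("classify", t0, [cls_path])

    # ---- projections and genomaps --------------------------------------
    if {"project", "genomap"} & set(stages):
        t0 = time.time()
        ct = config.panel_cell_type
        if ct is None and ds.cell_type_labels is not None:
            ct = str(sorted(set(ds.cell_type_labels))[0])
        panel = build_projection_panel(
            ctx["re"][0], ctx["fe"][0], ds, ctx["X"][0], cell_type=ct,
            n=config.panel_cells, seed=config.seed)
        panel_path = outdir / "projection_panel.csv"
        panel.to_csv(panel_path, outdir / "projection_panel_meta.json")
        outputs = [panel_path]
        vocab = ctx["re"][0].batch_vocab_
        if len(vocab) >= 2:
            half = len(vocab) // 2
            contrast = projection_contrast(panel, vocab[:half], vocab[half:])
            contrast_path = outdir / "projection_contrast.csv"
            contrast.to_csv(contrast_path, index=False)
            outputs.append(contrast_path)
        record("project", t0, outputs)

        if "genomap" in stages:
            t0 = time.time()
            layout = fit_genomap_layout(panel.matrix, gene_ids=panel.gene_ids)
            layout_path = outdir / "genomap_layout.csv"
            layout.to_frame().to_csv(layout_path, index=False)
            fig_path = outdir / "genomap_montage.png"
            genomap_montage(layout, panel.matrix, panel.metadata, fig_path)
            record("genomap", t0, [layout_path])

    manifest.write(outdir / "manifest.json")
    return manifest


def _round_1sf(x: float) -> float:
    if x == 0 or not np.isfinite(x):
        return 1.0
    return float(np.round(x, -int(np.floor(np.log10(abs(x))))))


def suggest_loss_weights(X: np.ndarray, design: BatchDesign,
                         labels=None, probe_epochs: int = 5,
                         fe_config: FEConfig | None = None,
                         re_config: REConfig | None = None
                         ) -> tuple[dict[str, float], pd.DataFrame]:
    """Balance loss-term weights by short unit-weight probe runs.

    Trains each subnetwork for ``probe_epochs`` with every weight at 1,
    records the mean magnitude of each loss term over the probe, and
    suggests weights that rescale each non-reconstruction term to the
    reconstruction term's magnitude, rounded to one significant figure.
    Terms with zero probe magnitude keep weight 1 with a warning.
    """
    if probe_epochs < 1:
        raise ValueError("probe_epochs must be >= 1")
    fe_config = fe_config or FEConfig()
    re_config = re_config or REConfig()
    fe_kwargs = {**asdict(fe_config), "lambda_recon_f": 1.0, "lambda_a": 1.0,
                 "lambda_y": 1.0 if labels is not None else 0.0,
                 "max_epochs": probe_epochs + 1, "patience": probe_epochs}
    re_kwargs = {**asdict(re_config), "lambda_recon_r": 1.0, "lambda_l": 1.0,
                 "lambda_k": 1.0, "max_epochs": probe_epochs + 1,
                 "patience": probe_epochs}
    try:
        fe = FixedEffectsAutoencoder(**fe_kwargs).fit(X, design=design, labels=labels)
        rem = RandomEffectsAutoencoder(**re_kwargs).fit(X, design=design)
    except RuntimeError as err:
        raise RuntimeError(
            f"probe run diverged ({err}); retry with a smaller learning rate") from err

    fe_h = fe.history_.head(probe_epochs)
    re_h = rem.history_.head(probe_epochs)
    mags = {
        "fe_recon": float(fe_h["train_recon"].abs().mean()),
        "fe_adversarial": float(fe_h["train_adversarial"].abs().mean()),
        "fe_celltype": float(fe_h["train_celltype"].abs().mean()),
        "re_recon": float(re_h["train_recon"].abs().mean()),
        "re_batch_ce": float(re_h["train_batch_ce"].abs().mean()),
        "re_kl": float(re_h["train_kl"].abs().mean()),
    }
    suggestions: dict[str, float] = {"lambda_recon_f": 1.0, "lambda_recon_r": 1.0}
    for lam, num, den in (("lambda_a", "fe_recon", "fe_adversarial"),
                          ("lambda_l", "re_recon", "re_batch_ce"),
                          ("lambda_k", "re_recon", "re_kl")):
        if mags[den] == 0:
            warnings.warn(f"{den} magnitude is zero; leaving {lam} at 1", stacklevel=2)
            suggestions[lam] = 1.0
        else:
            suggestions[lam] = _round_1sf(mags[num] / mags[den])
    if labels is not None:
        suggestions["lambda_y"] = (_round_1sf(mags["fe_recon"] / mags["fe_celltype"])
                                   if mags["fe_celltype"] > 0 else 1.0)
    table = pd.DataFrame(
        [{"term": k, "mean_magnitude": v} for k, v in mags.items()])
    return suggestions, table
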
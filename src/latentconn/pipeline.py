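"""End-to-end orchestration: simulate → residualize → train → attribute →
group stats → CCA, from a single config with hierarchical seeding.

Every source of randomness derives from the master seed through
numpy SeedSequence spawning, so each stage is independently reproducible
and two runs with the same config are identical. Each stage writes its
outputs under the run directory; a manifest with checksums is written at
the end.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from latentconn.attribution import IGConfig, attribute_cohort, znormalize
from latentconn.autoencoder import (
    EncoderSpec,
    GroupModelSet,
    evaluate_group_models,
    train_group_models,
)
from latentconn.cca import CCAConfig, association_feature_modes
from latentconn.data import EdgeTable, ParcelScheme, residualize_confounds
from latentconn.stats import compare_feature_modes
from latentconn.synthetic import (
    SyntheticConfig,
    cohort_edge_tables,
    generate_cohort,
    plant_behavior,
    write_cohort,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "residualize", "train", "attribute", "groupdiff", "cca")


@dataclass
class PipelineConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    encoder: EncoderSpec = field(default_factory=EncoderSpec)
    ig: IGConfig = field(default_factory=IGConfig)
    cca: CCAConfig = field(default_factory=CCAConfig)
    n_perm: int = 1000
    q: float = 0.05
    n_repeats: int = 1
    split_counts: dict[str, tuple[int, int, int]] | None = None
    planted_behavior_corrs: list[float] = field(default_factory=lambda: [0.8])
    behavior_noise_sd: float = 1.0
    feature_modes: list[str] = field(
        default_factory=lambda: ["attributions", "connectivity"]
    )
    seed: int = 0
    outdir: str = "latentconn_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "synthetic" in kwargs:
            kwargs["synthetic"] = SyntheticConfig(**kwargs["synthetic"])
        if "encoder" in kwargs:
            kwargs["encoder"] = EncoderSpec(**kwargs["encoder"])
        if "ig" in kwargs:
            kwargs["ig"] = IGConfig(**kwargs["ig"])
        if "cca" in kwargs:
            kwargs["cca"] = CCAConfig(**kwargs["cca"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        def plain(obj):
            if dataclasses.is_dataclass(obj):
                return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        return {
            "synthetic": plain(self.synthetic),
            "encoder": plain(self.encoder),
            "ig": plain(self.ig),
            "cca": plain(self.cca),
            "n_perm": self.n_perm,
            "q": self.q,
            "n_repeats": self.n_repeats,
            "split_counts": plain(self.split_counts),
            "planted_behavior_corrs": list(self.planted_behavior_corrs),
            "behavior_noise_sd": self.behavior_noise_sd,
            "feature_modes": list(self.feature_modes),
            "seed": self.seed,
            "outdir": str(self.outdir),
        }


@dataclass
class PipelineState:
    """In-memory artifacts shared across stages."""

    scheme: ParcelScheme | None = None
    phenotype: pd.DataFrame | None = None
    behavior: pd.DataFrame | None = None
    edge_tables_raw: dict[str, EdgeTable] | None = None
    edge_tables: dict[str, EdgeTable] | None = None  # residualized
    combined_raw: EdgeTable | None = None
    model_set: GroupModelSet | None = None
    recon: dict | None = None
    attributions_z: object | None = None
    truth: object | None = None
    groupdiff: dict | None = None
    cca_results: dict | None = None


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def _stage_simulate(cfg: PipelineConfig, state: PipelineState, outdir: Path) -> None:
    syn = dataclasses.replace(cfg.synthetic, seed=_stage_seed(cfg.seed, "simulate"))
    phenotype, matrices, truth = generate_cohort(syn)
    scheme = ParcelScheme.default(syn.n_parcels)
    left, right, combined = cohort_edge_tables(matrices, scheme)
    autism_rows = np.flatnonzero(phenotype["group"].to_numpy() == "autism")
    behavior = None
    if cfg.planted_behavior_corrs:
        aut_ids = [combined.subjects[i] for i in autism_rows]
        behavior, loadings = plant_behavior(
            combined.values[autism_rows],
            cfg.planted_behavior_corrs,
            noise_sd=cfg.behavior_noise_sd,
            seed=_stage_seed(cfg.seed, "behavior"),
            subject_ids=aut_ids,
        )
        truth.planted_canonical_corrs = list(cfg.planted_behavior_corrs)
    write_cohort(outdir, phenotype, matrices, truth, behavior=behavior)
    scheme.to_tsv(outdir / "parcel_scheme.tsv")
    state.scheme = scheme
    state.phenotype = phenotype
    state.behavior = behavior
    state.edge_tables_raw = {"L": left, "R": right}
    state.combined_raw = combined
    state.truth = truth


def _stage_residualize(cfg: PipelineConfig, state: PipelineState, outdir: Path) -> None:
    resid = {
        h: residualize_confounds(t, state.phenotype)
        for h, t in state.edge_tables_raw.items()
    }
    for h, t in resid.items():
        t.to_tsv(outdir / f"residual_edges_{h}.tsv")
    state.edge_tables = resid


def _stage_train(cfg: PipelineConfig, state: PipelineState, outdir: Path) -> None:
    labels = state.phenotype["group"].to_numpy()
    state.model_set = train_group_models(
        state.edge_tables,
        labels,
        cfg.encoder,
        counts=cfg.split_counts,
        n_repeats=cfg.n_repeats,
        seed=_stage_seed(cfg.seed, "train"),
    )
    state.recon = evaluate_group_models(state.model_set, state.edge_tables, labels)
    report = {g: {"mean_r": m, "sd_r": s} for g, (m, s) in state.recon.items()}
    (outdir / "reconstruction.json").write_text(json.dumps(report, indent=2))
    traces = []
    for (g, h), models in state.model_set.models.items():
        for rep, model in enumerate(models):
            df = pd.DataFrame(model.loss_trace, columns=["train_loss", "val_loss"])
            df.insert(0, "epoch", np.arange(len(df)))
            df.insert(0, "repeat", rep)
            df.insert(0, "hemisphere", h)
            df.insert(0, "group", g)
            df["selected"] = df["epoch"] == model.selected_epoch
            traces.append(df)
    pd.concat(traces).to_csv(outdir / "loss_traces.tsv", sep="\t", index=False)


def _stage_attribute(cfg: PipelineConfig, state: PipelineState, outdir: Path) -> None:
    labels = state.phenotype["group"].to_numpy()
    raw = attribute_cohort(state.model_set, state.edge_tables, labels, cfg.ig)
    z = znormalize(raw)
    raw.to_tsv(outdir / "attributions_raw.tsv")
    z.to_tsv(outdir / "attributions_z.tsv")
    state.attributions_z = z


def _edge_networks(state: PipelineState) -> np.ndarray:
    combined = state.combined_raw
    return combined.edge_networks(state.scheme)


def _stage_groupdiff(cfg: PipelineConfig, state: PipelineState, outdir: Path) -> None:
    labels = state.phenotype["group"].to_numpy()
    nets = _edge_networks(state)
    modes = {}
    if "attributions" in cfg.feature_modes:
        modes["attributions"] = state.attributions_z.values
    if "connectivity" in cfg.feature_modes:
        modes["connectivity"] = np.hstack(
            [state.edge_tables[h].values for h in ("L", "R")]
        )
    results = compare_feature_modes(
        modes, labels, nets, n_perm=cfg.n_perm, q=cfg.q,
        seed=_stage_seed(cfg.seed, "groupdiff"),
    )
    meta = {"seed": _stage_seed(cfg.seed, "groupdiff"), "n_perm": cfg.n_perm, "q": cfg.q}
    (outdir / "groupdiff_meta.json").write_text(json.dumps(meta))
    from latentconn.stats import summarize_networks

    for mode, (res, summary) in results.items():
        res.to_frame(state.attributions_z.edge_index).to_csv(
            outdir / f"groupdiff_{mode}.tsv", sep="\t", index=False
        )
        summary.matrix.to_csv(outdir / f"block_summary_{mode}.tsv", sep="\t")
        counts = summarize_networks(res.t, res.mask, nets, rule="count")
        counts.matrix.to_csv(outdir / f"block_count_{mode}.tsv", sep="\t")
    state.groupdiff = results


def _latent_features(state: PipelineState) -> np.ndarray:
    """Per-subject bottleneck codes, averaged over repeats, hemispheres
    concatenated."""
    labels = state.phenotype["group"].to_numpy()
    model_set = state.model_set
    blocks = []
    for hemi in model_set.hemispheres:
        table = state.edge_tables[hemi]
        acc = None
        for g in model_set.groups:
            rows = np.flatnonzero(labels == g)
            for model in model_set.models[(g, hemi)]:
                z = model.encode(model.scaler.transform(table.values[rows]))
                if acc is None:
                    acc = np.zeros((table.n_subjects, z.shape[1]))
                acc[rows] += z / len(model_set.models[(g, hemi)])
        blocks.append(acc)
    return np.hstack(blocks)


def _stage_cca(cfg: PipelineConfig, state: PipelineState, outdir: Path) -> None:
    if state.behavior is None:
        logger.info("no behavior scores available; CCA stage skipped")
        (outdir / "cca_skipped.json").write_text(
            json.dumps({"reason": "no behavior scores available"})
        )
        return
    labels = state.phenotype["group"].to_numpy()
    autism_rows = np.flatnonzero(labels == "autism")
    nets = _edge_networks(state)
    mode_features = {}
    mode_nets = {}
    if "attributions" in cfg.feature_modes:
        mode_features["attributions"] = state.attributions_z.values[autism_rows]
        mode_nets["attributions"] = nets
    if "connectivity" in cfg.feature_modes:
        mode_features["connectivity"] = np.hstack(
            [state.edge_tables[h].values[autism_rows] for h in ("L", "R")]
        )
        mode_nets["connectivity"] = nets
    if "latent" in cfg.feature_modes:
        mode_features["latent"] = _latent_features(state)[autism_rows]
    cca_cfg = dataclasses.replace(cfg.cca, seed=_stage_seed(cfg.seed, "cca"))
    behavior = state.behavior.set_index("subject_id").loc[
        [state.combined_raw.subjects[i] for i in autism_rows]
    ].reset_index()
    results, comparison = association_feature_modes(
        mode_features, behavior, cca_cfg, mode_edge_networks=mode_nets
    )
    comparison.to_csv(outdir / "cca_mode_comparison.tsv", sep="\t", index=False)
    for mode, res in results.items():
        res.component_table.to_csv(
            outdir / f"cca_components_{mode}.tsv", sep="\t", index=False
        )
        score_cols = [c for c in behavior.columns if c != "subject_id"]
        pd.Series(res.ev_scores, index=score_cols).to_csv(
            outdir / f"cca_ev_scores_{mode}.tsv", sep="\t", header=["ev"]
        )
        if res.block_ev is not None:
            res.block_ev.to_csv(outdir / f"cca_block_ev_{mode}.tsv", sep="\t")
    state.cca_results = results


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "residualize": _stage_residualize,
    "train": _stage_train,
    "attribute": _stage_attribute,
    "groupdiff": _stage_groupdiff,
    "cca": _stage_cca,
}


def run_pipeline(
    config: PipelineConfig, last_stage: str = "cca"
) -> tuple[Path, PipelineState]:
    """Run all stages through ``last_stage``; returns (outdir, state).

    A stage failure halts the run with the stage name; the manifest then
    covers the files written so far.
    """
    if last_stage not in STAGES:
        raise ValueError(f"unknown stage '{last_stage}'")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    state = PipelineState()
    records = []
    try:
        for stage in STAGES:
            t0 = time.time()
            logger.info("stage %s ...", stage)
            _STAGE_FNS[stage](config, state, outdir)
            records.append({"stage": stage, "seconds": round(time.time() - t0, 3)})
            if stage == last_stage:
                break
    except Exception as exc:
        _write_manifest(outdir, records, failed_stage=stage, error=str(exc))
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    _write_manifest(outdir, records)
    return outdir, state


def _write_manifest(
    outdir: Path, records: list, failed_stage: str | None = None, error: str | None = None
) -> None:
    files = {}
    for f in sorted(outdir.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            files[str(f.relative_to(outdir))] = hashlib.sha256(
                f.read_bytes()
            ).hexdigest()
    from latentconn import __version__

    manifest = {
        "version": __version__,
        "stages": records,
        "files": files,
    }
    if failed_stage:
        manifest["failed_stage"] = failed_stage
        manifest["error"] = error
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def sensitivity_sweep(
    config: PipelineConfig, grid: list[dict]
) -> pd.DataFrame:
    """Reconstruction performance across encoder hyperparameter variants.

    ``grid`` lists EncoderSpec field overrides (e.g. unit counts, dropout,
    learning rate, layer count). Duplicate variants are deduplicated;
    infeasible variants (nonpositive layer sizes) are skipped with a
    warning. The cohort and splits are shared across variants. Returns one
    row per variant with the per-group mean/SD test reconstruction r.
    """
    seen = set()
    variants = []
    for g in grid:
        key = tuple(sorted((k, str(v)) for k, v in g.items()))
        if key not in seen:
            seen.add(key)
            variants.append(g)
    base, state = run_pipeline(config, last_stage="residualize")
    labels = state.phenotype["group"].to_numpy()
    rows = []
    for variant in variants:
        try:
            spec = dataclasses.replace(config.encoder, **variant)
            spec.validate()
        except (TypeError, ValueError) as exc:
            logger.warning("skipping infeasible variant %s: %s", variant, exc)
            continue
        model_set = train_group_models(
            state.edge_tables,
            labels,
            spec,
            counts=config.split_counts,
            n_repeats=config.n_repeats,
            seed=_stage_seed(config.seed, "train"),
        )
        recon = evaluate_group_models(model_set, state.edge_tables, labels)
        row = {"variant": json.dumps(variant, sort_keys=True)}
        for g, (m, s) in recon.items():
            row[f"mean_r_{g}"] = m
            row[f"sd_r_{g}"] = s
        rows.append(row)
    table = pd.DataFrame(rows)
    table.to_csv(Path(config.outdir) / "sensitivity_sweep.tsv", sep="\t", index=False)
    return table
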
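"""Synthetic connectome cohorts with known ground truth.

Emulates the structure of a two-group (autism / control) diffusion-MRI
cohort: symmetric nonnegative log-weight connectivity over an even
parcellation split 50/50 by hemisphere, low-rank latent structure shared
across subjects, additive linear age/sex/site confound effects on edges,
group-specific mean shifts confined to chosen community blocks, and
behavior scores with a planted canonical correlation to edge features.

The low-rank factor model gives the autoencoder genuine structure to learn;
confounds act additively and linearly so OLS residualization can remove
them exactly; a sharp softplus keeps weights nonnegative while preserving
planted mean shifts to high accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from latentconn.data import (
    NETWORKS,
    ConnectivityMatrix,
    EdgeTable,
    ParcelScheme,
    build_edge_table,
    concat_hemispheres,
    devectorize,
    triu_indices,
)

SITES = ("NYU", "TCD", "SDSU")
BEHAVIOR_COLUMNS = ("ados_total", "ados_social", "ados_comm", "ados_rep")

#: Mean of the latent log-weight scale before the nonnegativity transform.
BASELINE_WEIGHT = 3.0
#: Sharpness of the softplus used to enforce nonnegativity; at the baseline
#: weight scale the transform is the identity to ~1e-5.
SOFTPLUS_BETA = 4.0


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    ``effect_blocks`` lists ``(network_a, network_b, delta)`` triples: the
    autism group's edges inside each block are shifted by ``delta`` (same
    shift in both hemispheres). ``confound_betas`` holds scalar scales for
    the additive linear age / sex / site effects; each edge gets its own
    standard-normal direction so confounds are spread across the matrix.
    """

    n_autism: int = 80
    n_control: int = 61
    n_parcels: int = 200
    latent_rank: int = 5
    effect_blocks: list[tuple[str, str, float]] = field(default_factory=list)
    confound_betas: dict[str, float] = field(
        default_factory=lambda: {"age": 0.02, "sex": 0.1, "site": 0.1}
    )
    noise_sd: float = 0.2
    latent_sd: float = 0.5
    behavior_loadings: np.ndarray | None = None
    behavior_noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_parcels % 2 != 0:
            raise ValueError("n_parcels must be even")
        if self.n_autism < 1 or self.n_control < 1:
            raise ValueError("both groups need at least one subject")
        for a, b, delta in self.effect_blocks:
            if a not in NETWORKS or b not in NETWORKS:
                raise ValueError(
                    f"effect block ({a}, {b}) uses unknown network names; "
                    f"must be among {NETWORKS}"
                )
            if not np.isfinite(delta):
                raise ValueError(f"effect block ({a}, {b}) delta must be finite")
        if self.noise_sd < 0 or self.behavior_noise_sd < 0:
            raise ValueError("noise standard deviations must be nonnegative")


@dataclass
class GroundTruth:
    """What was planted: per-edge effect mask (combined L-then-R edge axis),
    planted canonical correlations, and the confound coefficients used."""

    effect_mask: np.ndarray
    planted_canonical_corrs: list[float]
    confound_betas: dict[str, float]
    edge_index: np.ndarray

    def to_json(self, path: str | Path) -> None:
        payload = {
            "effect_mask": self.effect_mask.astype(int).tolist(),
            "planted_canonical_corrs": list(self.planted_canonical_corrs),
            "confound_betas": self.confound_betas,
            "edge_index": self.edge_index.tolist(),
        }
        Path(path).write_text(json.dumps(payload))


def _softplus(x: np.ndarray, beta: float = SOFTPLUS_BETA) -> np.ndarray:
    # numerically stable log(1 + exp(beta x)) / beta
    return np.logaddexp(0.0, beta * x) / beta


def _block_mask(edge_networks: np.ndarray, net_a: str, net_b: str) -> np.ndarray:
    pair = tuple(sorted((net_a, net_b)))
    return np.array([tuple(e) == pair for e in edge_networks])


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, list[ConnectivityMatrix], GroundTruth]:
    """Draw a full synthetic cohort.

    Returns the phenotype table (subject_id, group, age, sex, site),
    one connectivity matrix per subject, and the planted ground truth.
    Fixed seed implies byte-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    scheme = ParcelScheme.default(config.n_parcels)
    p_hemi = config.n_parcels // 2
    n_edges_hemi = p_hemi * (p_hemi - 1) // 2
    n = config.n_autism + config.n_control

    subject_ids = [f"aut{i:04d}" for i in range(config.n_autism)] + [
        f"con{i:04d}" for i in range(config.n_control)
    ]
    group = np.array(["autism"] * config.n_autism + ["control"] * config.n_control)
    age = rng.uniform(8.0, 18.0, size=n)
    sex = rng.integers(0, 2, size=n)  # 0/1, roughly balanced
    site = rng.choice(SITES, size=n)

    # shared low-rank subject scores, per-hemisphere loadings
    scores = rng.standard_normal((n, config.latent_rank))
    betas = config.confound_betas
    site_dummies = np.column_stack([(site == s).astype(float) for s in SITES[1:]])

    hemi_edges: dict[str, np.ndarray] = {}
    hemi_edge_nets: dict[str, np.ndarray] = {}
    for hemi in ("L", "R"):
        loadings = rng.standard_normal((config.latent_rank, n_edges_hemi))
        loadings *= config.latent_sd / np.sqrt(config.latent_rank)
        edges = BASELINE_WEIGHT + scores @ loadings

        # additive linear confound effects, per-edge random direction
        age_dir = rng.standard_normal(n_edges_hemi)
        sex_dir = rng.standard_normal(n_edges_hemi)
        site_dir = rng.standard_normal((len(SITES) - 1, n_edges_hemi))
        edges += betas.get("age", 0.0) * np.outer(age - 13.0, age_dir)
        edges += betas.get("sex", 0.0) * np.outer(sex, sex_dir)
        edges += betas.get("site", 0.0) * site_dummies @ site_dir

        # group shifts confined to declared community blocks
        parcels = scheme.hemisphere_parcels(hemi)
        local_pairs = triu_indices(p_hemi)
        nets = scheme.networks
        edge_nets = np.array(
            [
                tuple(sorted((nets[parcels[i]], nets[parcels[j]])))
                for i, j in local_pairs
            ],
            dtype=object,
        )
        mask_total = np.zeros(n_edges_hemi, dtype=bool)
        for net_a, net_b, delta in config.effect_blocks:
            m = _block_mask(edge_nets, net_a, net_b)
            edges[group == "autism"] += delta * m
            mask_total |= m
        edges += rng.normal(0.0, config.noise_sd, size=edges.shape)
        hemi_edges[hemi] = _softplus(edges)
        hemi_edge_nets[hemi] = mask_total

    # inter-hemispheric entries: baseline + noise only (discarded downstream)
    inter = _softplus(
        BASELINE_WEIGHT
        + rng.normal(0.0, config.noise_sd, size=(n, p_hemi, p_hemi))
    )

    matrices = []
    left_ids = scheme.hemisphere_parcels("L")
    right_ids = scheme.hemisphere_parcels("R")
    for s in range(n):
        full = np.zeros((config.n_parcels, config.n_parcels))
        full[np.ix_(left_ids, left_ids)] = devectorize(hemi_edges["L"][s], p_hemi)
        full[np.ix_(right_ids, right_ids)] = devectorize(hemi_edges["R"][s], p_hemi)
        inter_s = inter[s]
        full[np.ix_(left_ids, right_ids)] = inter_s
        full[np.ix_(right_ids, left_ids)] = inter_s.T
        np.fill_diagonal(full, 0.0)
        matrices.append(ConnectivityMatrix(subject_id=subject_ids[s], values=full))

    phenotype = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "group": group,
            "age": age,
            "sex": sex,
            "site": site,
        }
    )
    effect_mask = np.concatenate([hemi_edge_nets["L"], hemi_edge_nets["R"]])
    local_pairs = triu_indices(p_hemi)
    edge_index = np.vstack([left_ids[local_pairs], right_ids[local_pairs]])
    truth = GroundTruth(
        effect_mask=effect_mask,
        planted_canonical_corrs=[],
        confound_betas=dict(betas),
        edge_index=edge_index,
    )
    return phenotype, matrices, truth


def generate_behavior(
    config: SyntheticConfig,
    edge_features: np.ndarray,
    subject_ids: list[str] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Behavior scores as a linear map of edge features plus noise.

    ``scores = features @ loadings + noise``; in the noiseless limit the
    canonical correlation between the feature space and the score space
    along each nonzero loading direction is 1.
    """
    if config.behavior_loadings is None:
        raise ValueError("config.behavior_loadings not set")
    loadings = np.asarray(config.behavior_loadings, dtype=float)
    if loadings.shape != (edge_features.shape[1], len(BEHAVIOR_COLUMNS)):
        raise ValueError(
            f"behavior_loadings shape {loadings.shape} does not match "
            f"({edge_features.shape[1]}, {len(BEHAVIOR_COLUMNS)})"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    scores = edge_features @ loadings
    scores += rng.normal(0.0, config.behavior_noise_sd, size=scores.shape)
    out = pd.DataFrame(scores, columns=list(BEHAVIOR_COLUMNS))
    if subject_ids is not None:
        out.insert(0, "subject_id", subject_ids)
    return out


def plant_behavior(
    edge_features: np.ndarray,
    target_corrs: list[float],
    noise_sd: float = 1.0,
    seed: int = 0,
    subject_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Build behavior scores whose canonical correlation with the features
    is planted at ``target_corrs``.

    Each target rho drives one score column: an orthonormal random direction
    w in feature space is projected (t = X w, standardized), scaled so that
    signal/noise gives corr(t, score) = rho, and iid noise of ``noise_sd``
    is added. Remaining score columns are pure noise. Returns the behavior
    table and the loading matrix actually used.
    """
    n, d = edge_features.shape
    k = len(target_corrs)
    if k > len(BEHAVIOR_COLUMNS):
        raise ValueError(f"at most {len(BEHAVIOR_COLUMNS)} planted correlations")
    rng = np.random.default_rng(seed)
    Xc = edge_features - edge_features.mean(axis=0)
    raw_dirs = rng.standard_normal((d, k))
    dirs, _ = np.linalg.qr(raw_dirs)
    loadings = np.zeros((d, len(BEHAVIOR_COLUMNS)))
    for j, rho in enumerate(target_corrs):
        if not 0 <= rho < 1:
            raise ValueError("planted correlations must be in [0, 1)")
        t = Xc @ dirs[:, j]
        sd_t = t.std()
        if sd_t == 0:
            raise ValueError("degenerate feature projection (zero variance)")
        # corr(a·t, a·t + eps) = rho  <=>  a·sd_t = noise_sd · rho / sqrt(1 - rho²)
        scale = noise_sd * rho / np.sqrt(1.0 - rho**2) / sd_t
        loadings[:, j] = dirs[:, j] * scale
    scores = edge_features @ loadings
    scores += rng.normal(0.0, noise_sd, size=scores.shape)
    out = pd.DataFrame(scores, columns=list(BEHAVIOR_COLUMNS))
    if subject_ids is not None:
        out.insert(0, "subject_id", subject_ids)
    return out, loadings


def cohort_edge_tables(
    matrices: list[ConnectivityMatrix], scheme: ParcelScheme
) -> tuple[EdgeTable, EdgeTable, EdgeTable]:
    """Vectorized (left, right, combined) edge tables for a cohort."""
    left = build_edge_table(matrices, scheme, "L")
    right = build_edge_table(matrices, scheme, "R")
    return left, right, concat_hemispheres(left, right)


def write_cohort(
    outdir: str | Path,
    phenotype: pd.DataFrame,
    matrices: list[ConnectivityMatrix],
    truth: GroundTruth,
    behavior: pd.DataFrame | None = None,
) -> None:
    """Write phenotype TSV, per-subject connectivity TSVs, ground-truth JSON
    and optionally the behavior TSV under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    phenotype.to_csv(outdir / "phenotype.tsv", sep="\t", index=False)
    conndir = outdir / "connectivity"
    conndir.mkdir(exist_ok=True)
    for m in matrices:
        np.savetxt(conndir / f"{m.subject_id}.tsv", m.values, delimiter="\t")
    truth.to_json(outdir / "ground_truth.json")
    if behavior is not None:
        behavior.to_csv(outdir / "behavior.tsv", sep="\t", index=False)
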
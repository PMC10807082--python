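"""Canonical correlation analysis linking edge features to symptom scores.

Classical CCA via SVD of the whitened cross-covariance: with centered
views X and Y, economy SVDs X = Ux Sx Vx' and Y = Uy Sy Vy' give
K = Ux' Uy whose singular value decomposition U diag(rho) V' yields the
canonical correlations rho (non-increasing by construction) and weights
Wx = Vx Sx^{-1} U, Wy = Vy Sy^{-1} V. Because edges far outnumber
subjects, X is reduced by PCA (retaining min(n/2, 50) components by
default) before CCA, and weights are back-projected to edge space for
explained-variance summaries.

The number of informative components is chosen by five-fold
cross-validation: per fold, the model is fit on training rows, held-out
rows are projected, and the held-out correlation of each canonical pair is
tested by permuting the held-out rows of one view (add-one two-tailed
p-values, BH-FDR across components); a component counts as selected when
significant in a majority of folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from latentconn.data import NETWORKS
from latentconn.stats import fdr_bh

logger = logging.getLogger(__name__)


@dataclass
class CCAConfig:
    n_folds: int = 5
    max_components: int = 4
    fdr_q: float = 0.05
    x_reduction: int | None = None  # None = min(n // 2, 50, dims)
    n_perm: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.max_components < 1:
            raise ValueError("max_components must be >= 1")


@dataclass
class CCAFit:
    """Weights and training-sample canonical structure for one fit."""

    x_weights: np.ndarray  # (d_x_reduced, k)
    y_weights: np.ndarray  # (d_y, k)
    corrs: np.ndarray  # (k,) training canonical correlations, non-increasing
    x_mean: np.ndarray
    y_mean: np.ndarray
    pca_components: np.ndarray | None  # (d_x_reduced, d_x_original)

    def transform(self, X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        Xc = X - self.x_mean
        if self.pca_components is not None:
            Xc = Xc @ self.pca_components.T
        return Xc @ self.x_weights, (Y - self.y_mean) @ self.y_weights

    def x_weights_full(self) -> np.ndarray:
        """Canonical X weights back-projected to the original feature space."""
        if self.pca_components is None:
            return self.x_weights
        return self.pca_components.T @ self.x_weights


@dataclass
class CCAResult:
    fit: CCAFit
    component_table: pd.DataFrame  # fold, component, heldout r, p, q, significant
    selected: int
    ev_scores: np.ndarray | None = None
    ev_features: np.ndarray | None = None
    block_ev: pd.DataFrame | None = None


def _center(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = A.mean(axis=0)
    return A - mean, mean


def _pca_reduce(Xc: np.ndarray, n_components: int) -> tuple[np.ndarray, np.ndarray]:
    """PCA scores and components of centered data via economy SVD."""
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components, (S > 1e-12 * S[0]).sum())
    return Xc @ Vt[:k].T, Vt[:k]


def fit_cca(X: np.ndarray, Y: np.ndarray, config: CCAConfig | None = None) -> CCAFit:
    """Fit classical CCA (after PCA reduction of X when wide).

    Raises if either view is singular after reduction, advising stronger
    reduction.
    """
    config = config or CCAConfig()
    config.validate()
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have aligned rows")
    n = X.shape[0]
    Xc, x_mean = _center(X)
    Yc, y_mean = _center(Y)
    pca_components = None
    target_dim = config.x_reduction or min(n // 2, 50, X.shape[1])
    if X.shape[1] > target_dim:
        Xc, pca_components = _pca_reduce(Xc, target_dim)
    k = min(config.max_components, Xc.shape[1], Yc.shape[1])
    Ux, Sx, Vxt = np.linalg.svd(Xc, full_matrices=False)
    Uy, Sy, Vyt = np.linalg.svd(Yc, full_matrices=False)
    tol_x = 1e-10 * (Sx[0] if Sx.size else 1.0)
    tol_y = 1e-10 * (Sy[0] if Sy.size else 1.0)
    rx, ry = int((Sx > tol_x).sum()), int((Sy > tol_y).sum())
    if rx < k or ry < k:
        raise np.linalg.LinAlgError(
            f"singular covariance after reduction (ranks {rx}, {ry} < {k} "
            "components); reduce X more aggressively or drop components"
        )
    K = Ux[:, :rx].T @ Uy[:, :ry]
    U, rho, Vt = np.linalg.svd(K)
    rho = np.clip(rho[:k], 0.0, 1.0)
    # weights in (reduced) view space; canonical variates have unit norm
    Wx = Vxt[:rx].T @ (U[:, :k] / Sx[:rx, None])
    Wy = Vyt[:ry].T @ (Vt[:k].T / Sy[:ry, None])
    return CCAFit(
        x_weights=Wx,
        y_weights=Wy,
        corrs=rho,
        x_mean=x_mean,
        y_mean=y_mean,
        pca_components=pca_components,
    )


def _heldout_component_pvals(
    u: np.ndarray, v: np.ndarray, n_perm: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Held-out correlation per component and permutation p-values obtained
    by permuting the held-out rows of v (shared permutations across
    components, add-one two-tailed)."""
    k = u.shape[1]
    r_obs = np.array([_safe_corr(u[:, c], v[:, c]) for c in range(k)])
    exceed = np.zeros(k)
    for _ in range(n_perm):
        perm = rng.permutation(u.shape[0])
        r_perm = np.array([_safe_corr(u[:, c], v[perm, c]) for c in range(k)])
        exceed += np.abs(r_perm) >= np.abs(r_obs)
    return r_obs, (1.0 + exceed) / (n_perm + 1.0)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def select_components(
    X: np.ndarray, Y: np.ndarray, config: CCAConfig | None = None
) -> tuple[int, pd.DataFrame]:
    """Cross-validated canonical component count.

    Returns the selected count and the per-fold component table
    (fold, component, held-out r, p, q-adjusted, significant).
    """
    config = config or CCAConfig()
    config.validate()
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    if n < 2 * config.n_folds:
        raise ValueError(f"need at least {2 * config.n_folds} rows for {config.n_folds} folds")
    kf = KFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    rng = np.random.default_rng(config.seed + 1)
    rows = []
    sig_counts = None
    for fold, (tr, te) in enumerate(kf.split(X)):
        if len(te) < 3:
            raise ValueError(f"fold {fold} has only {len(te)} held-out rows (< 3)")
        fit = fit_cca(X[tr], Y[tr], config)
        u, v = fit.transform(X[te], Y[te])
        r_obs, p = _heldout_component_pvals(u, v, config.n_perm, rng)
        mask, adjusted = fdr_bh(p, config.fdr_q)
        if sig_counts is None:
            sig_counts = np.zeros(len(r_obs), dtype=int)
        sig_counts += mask.astype(int)
        for c in range(len(r_obs)):
            rows.append((fold, c, r_obs[c], p[c], adjusted[c], bool(mask[c])))
    table = pd.DataFrame(
        rows, columns=["fold", "component", "heldout_r", "p", "p_adjusted", "significant"]
    )
    majority = config.n_folds // 2 + 1
    selected = int((sig_counts >= majority).sum())
    return selected, table


def explained_variance(x: np.ndarray, x_hat: np.ndarray) -> float:
    """EV = (Var{x} - Var{x - x_hat}) / Var{x}, population variances.

    1 iff the prediction matches up to a constant; 0 for the mean
    predictor; negative for predictions worse than the mean. Undefined
    (NaN) when Var{x} = 0.
    """
    x = np.asarray(x, dtype=float).ravel()
    x_hat = np.asarray(x_hat, dtype=float).ravel()
    if x.shape != x_hat.shape:
        raise ValueError("x and x_hat must have the same shape")
    var_x = x.var()
    if var_x == 0:
        return float("nan")
    return float((var_x - (x - x_hat).var()) / var_x)


def _regress_predict(scores: np.ndarray, target_centered: np.ndarray) -> np.ndarray:
    """Least-squares prediction of a centered view from canonical scores."""
    coef, *_ = np.linalg.lstsq(scores, target_centered, rcond=None)
    return scores @ coef


def ev_profile(
    X: np.ndarray,
    Y: np.ndarray,
    fit: CCAFit,
    selected: int,
    edge_networks: np.ndarray | None = None,
    score_names: list[str] | None = None,
) -> tuple[pd.Series, np.ndarray, pd.DataFrame | None]:
    """Explained-variance profile of a fitted CCA.

    Y scores are predicted from the X-side canonical variates u, and X
    features from the Y-side variates v (cross-view prediction, restricted
    to the ``selected`` components), so EV measures behavior-linked
    variance. Returns (per-score EV, per-feature EV, 7x7 block mean-EV
    table or None).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    names = score_names or [f"score_{j}" for j in range(Y.shape[1])]
    if selected == 0:
        ev_scores = pd.Series(np.zeros(Y.shape[1]), index=names)
        ev_feat = np.zeros(X.shape[1])
    else:
        u, v = fit.transform(X, Y)
        u, v = u[:, :selected], v[:, :selected]
        Yc = Y - Y.mean(axis=0)
        Xc = X - X.mean(axis=0)
        y_hat = _regress_predict(u, Yc)
        x_hat = _regress_predict(v, Xc)
        ev_scores = pd.Series(
            [explained_variance(Yc[:, j], y_hat[:, j]) for j in range(Y.shape[1])],
            index=names,
        )
        ev_feat = np.array(
            [explained_variance(Xc[:, j], x_hat[:, j]) for j in range(X.shape[1])]
        )
    block = None
    if edge_networks is not None:
        block = pd.DataFrame(np.nan, index=list(NETWORKS), columns=list(NETWORKS))
        for i, na in enumerate(NETWORKS):
            for nb in NETWORKS[i:]:
                pair = tuple(sorted((na, nb)))
                in_block = np.array([tuple(e) == pair for e in edge_networks])
                if in_block.any():
                    val = float(np.nanmean(ev_feat[in_block]))
                    block.loc[na, nb] = val
                    block.loc[nb, na] = val
    return ev_scores, ev_feat, block


def analyze(
    X: np.ndarray,
    Y: np.ndarray,
    config: CCAConfig | None = None,
    edge_networks: np.ndarray | None = None,
    score_names: list[str] | None = None,
) -> CCAResult:
    """Full CCA analysis: component selection, full-sample fit, EV profile."""
    config = config or CCAConfig()
    selected, table = select_components(X, Y, config)
    fit = fit_cca(X, Y, config)
    ev_scores, ev_feat, block = ev_profile(
        X, Y, fit, selected, edge_networks=edge_networks, score_names=score_names
    )
    return CCAResult(
        fit=fit,
        component_table=table,
        selected=selected,
        ev_scores=ev_scores.to_numpy(),
        ev_features=ev_feat,
        block_ev=block,
    )


def association_feature_modes(
    mode_features: dict[str, np.ndarray],
    behavior: pd.DataFrame,
    config: CCAConfig | None = None,
    mode_edge_networks: dict[str, np.ndarray] | None = None,
) -> tuple[dict[str, CCAResult], pd.DataFrame]:
    """Run the identical CCA machinery per feature mode.

    ``behavior`` may contain NaN rows (subjects without scores); those rows
    are dropped from every mode with a logged count. Returns per-mode
    results and a comparison table of mean held-out correlations.
    """
    config = config or CCAConfig()
    score_cols = [c for c in behavior.columns if c != "subject_id"]
    Y = behavior[score_cols].to_numpy(dtype=float)
    keep = ~np.isnan(Y).any(axis=1)
    if (~keep).sum():
        logger.info("dropping %d subjects without behavior scores", int((~keep).sum()))
    Y = Y[keep]
    results = {}
    rows = []
    for mode, X in mode_features.items():
        X = np.asarray(X, dtype=float)[keep]
        nets = (mode_edge_networks or {}).get(mode)
        res = analyze(X, Y, config, edge_networks=nets, score_names=score_cols)
        results[mode] = res
        mean_r = (
            res.component_table.groupby("component")["heldout_r"].mean().to_numpy()
        )
        for c, r in enumerate(mean_r):
            rows.append((mode, c, r, res.selected))
    comparison = pd.DataFrame(
        rows, columns=["mode", "component", "mean_heldout_r", "selected"]
    )
    return results, comparison
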
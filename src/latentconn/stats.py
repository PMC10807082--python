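"""Edgewise group comparison: permutation t-tests, FDR, network blocks.

Two-sample pooled-variance t-statistics per edge; a permutation null built
by randomly reassigning group labels (the same permutations shared across
edges within a run); two-tailed add-one p-values p = (1 + #{|t*| >= |t|})
/ (n_perm + 1); Benjamini-Hochberg FDR across all edges jointly; and a
7x7 functional-community block summary of the significant edges' t-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from latentconn.data import NETWORKS


@dataclass
class GroupDiffResult:
    t: np.ndarray
    p: np.ndarray
    p_adjusted: np.ndarray
    mask: np.ndarray
    q: float
    n_permutations: int
    seed: int
    group_a: str = "A"
    group_b: str = "B"

    def to_frame(self, edge_index: np.ndarray | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "t": self.t,
                "p": self.p,
                "p_adjusted": self.p_adjusted,
                "significant": self.mask,
            }
        )
        if edge_index is not None:
            df.insert(0, "parcel_i", edge_index[:, 0])
            df.insert(1, "parcel_j", edge_index[:, 1])
        return df


@dataclass
class NetworkSummary:
    """7x7 symmetric block summary; blocks with no significant edges are
    flagged in ``empty_blocks`` and hold NaN, never a silent zero."""

    matrix: pd.DataFrame
    rule: str
    empty_blocks: list[tuple[str, str]] = field(default_factory=list)

    def block(self, net_a: str, net_b: str) -> float:
        return float(self.matrix.loc[net_a, net_b])


def _tstat(
    values: np.ndarray, a_mask: np.ndarray, b_mask: np.ndarray, warn: bool = True
) -> np.ndarray:
    """Vectorized pooled-variance two-sample t per column; sign = A - B."""
    A, B = values[a_mask], values[b_mask]
    na, nb = A.shape[0], B.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("each group needs >= 2 subjects")
    va = A.var(axis=0, ddof=1)
    vb = B.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    zero = denom == 0
    if zero.any() and warn:
        warnings.warn(f"{int(zero.sum())} edges with zero pooled variance; t set to 0")
    diff = A.mean(axis=0) - B.mean(axis=0)
    return np.where(zero, 0.0, diff / np.where(zero, 1.0, denom))


def _welch_tstat(
    values: np.ndarray, a_mask: np.ndarray, b_mask: np.ndarray, warn: bool = True
) -> np.ndarray:
    A, B = values[a_mask], values[b_mask]
    na, nb = A.shape[0], B.shape[0]
    denom = np.sqrt(A.var(axis=0, ddof=1) / na + B.var(axis=0, ddof=1) / nb)
    zero = denom == 0
    diff = A.mean(axis=0) - B.mean(axis=0)
    return np.where(zero, 0.0, diff / np.where(zero, 1.0, denom))


def edgewise_ttest(
    values_a: np.ndarray, values_b: np.ndarray, variant: str = "pooled"
) -> np.ndarray:
    """Two-sample t statistic per edge, sign = mean(A) - mean(B).

    ``variant``: "pooled" (classical two-sample t, default) or "welch".
    """
    values_a = np.atleast_2d(values_a)
    values_b = np.atleast_2d(values_b)
    stacked = np.vstack([values_a, values_b])
    a_mask = np.zeros(stacked.shape[0], dtype=bool)
    a_mask[: values_a.shape[0]] = True
    fn = _tstat if variant == "pooled" else _welch_tstat
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant '{variant}'")
    return fn(stacked, a_mask, ~a_mask)


def permutation_test(
    values: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    variant: str = "pooled",
) -> tuple[np.ndarray, np.ndarray]:
    """Two-tailed permutation p-values per edge.

    Group labels are randomly reassigned ``n_perm`` times (permutations
    shared across edges); p = (1 + #{permuted |t| >= observed |t|}) /
    (n_perm + 1), which cannot reach zero. Returns (t_observed, p).
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    labels = np.asarray(labels)
    levels = list(dict.fromkeys(labels))
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {len(levels)}")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives coarse p-value resolution")
    a_mask = labels == levels[0]
    fn = _tstat if variant == "pooled" else _welch_tstat
    t_obs = fn(values, a_mask, ~a_mask)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(values.shape[1])
    abs_obs = np.abs(t_obs)
    for _ in range(n_perm):
        perm_mask = np.zeros(len(labels), dtype=bool)
        perm_mask[rng.choice(len(labels), size=int(a_mask.sum()), replace=False)] = True
        t_perm = fn(values, perm_mask, ~perm_mask, warn=False)
        exceed += np.abs(t_perm) >= abs_obs
    p = (1.0 + exceed) / (n_perm + 1.0)
    return t_obs, p


def fdr_bh(pvals: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejection mask, adjusted p-values)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    mask, adjusted, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return mask, adjusted


def group_difference(
    values: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 1000,
    q: float = 0.05,
    seed: int = 0,
    variant: str = "pooled",
) -> GroupDiffResult:
    """Permutation t-test per edge with BH-FDR across all edges jointly."""
    t, p = permutation_test(values, labels, n_perm=n_perm, seed=seed, variant=variant)
    mask, adjusted = fdr_bh(p, q)
    levels = list(dict.fromkeys(np.asarray(labels)))
    return GroupDiffResult(
        t=t,
        p=p,
        p_adjusted=adjusted,
        mask=mask,
        q=q,
        n_permutations=n_perm,
        seed=seed,
        group_a=str(levels[0]),
        group_b=str(levels[1]),
    )


def summarize_networks(
    t: np.ndarray,
    mask: np.ndarray,
    edge_networks: np.ndarray,
    rule: str = "mean_t",
) -> NetworkSummary:
    """Summarize significant edges' t-values over the 28 community blocks.

    ``edge_networks`` holds the unordered (network_a, network_b) label per
    edge. ``rule``: "mean_t" (signed mean), "mean_abs_t", or "count".
    """
    if rule not in ("mean_t", "mean_abs_t", "count"):
        raise ValueError(f"unknown summary rule '{rule}'")
    for pair in edge_networks:
        for net in pair:
            if net not in NETWORKS:
                raise ValueError(f"unknown network label '{net}'")
    mat = pd.DataFrame(np.nan, index=list(NETWORKS), columns=list(NETWORKS))
    empty = []
    for i, na in enumerate(NETWORKS):
        for nb in NETWORKS[i:]:
            pair = tuple(sorted((na, nb)))
            in_block = np.array([tuple(e) == pair for e in edge_networks])
            sel = in_block & mask
            if rule == "count":
                val = float(sel.sum())
            elif not sel.any():
                empty.append((na, nb))
                val = np.nan
            elif rule == "mean_t":
                val = float(t[sel].mean())
            else:
                val = float(np.abs(t[sel]).mean())
            mat.loc[na, nb] = val
            mat.loc[nb, na] = val
    return NetworkSummary(matrix=mat, rule=rule, empty_blocks=empty)


def compare_feature_modes(
    mode_values: dict[str, np.ndarray],
    labels: np.ndarray,
    edge_networks: np.ndarray,
    n_perm: int = 1000,
    q: float = 0.05,
    seed: int = 0,
    rule: str = "mean_t",
) -> dict[str, tuple[GroupDiffResult, NetworkSummary]]:
    """Run the identical statistical machinery per feature mode (e.g.
    integrated-gradient attributions vs raw structural connectivity) for
    side-by-side block summaries."""
    out = {}
    for mode, values in mode_values.items():
        res = group_difference(values, labels, n_perm=n_perm, q=q, seed=seed)
        summary = summarize_networks(res.t, res.mask, edge_networks, rule=rule)
        out[mode] = (res, summary)
    return out
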
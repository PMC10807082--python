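"""Integrated-gradient attribution of input edges to the latent code.

For a differentiable target f and baseline m, the attribution of input
coordinate i is

    IG_i(x) = (x_i - m_i) * (1/M) * sum_{k=1..M} df(m + (k/M)(x - m)) / dx_i,

the right-endpoint Riemann approximation of the path integral of gradients
from the baseline to the input. The default target scalarizes the
bottleneck by summing its units, which preserves the completeness axiom
(attributions sum to f(x) - f(m)) against a single scalar; per-unit
attribution with subsequent aggregation of absolute values is available.
The default baseline is the all-zero ("zero-information") input; other
baselines can be supplied since attributions depend on this choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from latentconn.data import EdgeTable
from latentconn.autoencoder import GroupModelSet, TrainedModel

#: f_grad signature: X (B, d) -> (values (B,), grads (B, d))
TargetFn = Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]]


@dataclass
class IGConfig:
    baseline: np.ndarray | None = None  # None = all zeros
    steps: int = 300
    aggregation: str = "sum"  # "sum", "mean", or "per_unit"

    def validate(self) -> None:
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.aggregation not in ("sum", "mean", "per_unit"):
            raise ValueError(f"unknown aggregation '{self.aggregation}'")


@dataclass
class AttributionMatrix:
    """Subjects-by-edges integrated-gradient values."""

    values: np.ndarray
    subjects: list[str]
    edge_index: np.ndarray
    normalization: str = "raw"  # "raw" or "z"
    config: IGConfig | None = None

    def to_tsv(self, path) -> None:
        import pandas as pd

        cols = [f"e{i}_{j}" for i, j in self.edge_index]
        pd.DataFrame(self.values, index=self.subjects, columns=cols).to_csv(
            path, sep="\t", index_label="subject_id"
        )


def encoder_target(model: TrainedModel, aggregation: str = "sum") -> TargetFn:
    """Value-and-gradient closure for a trained encoder's scalarized code."""

    def f_grad(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return model.encoder_value_and_grad(X, aggregation=aggregation)

    return f_grad


def integrated_gradients(
    f_grad: TargetFn, X: np.ndarray, config: IGConfig | None = None
) -> np.ndarray:
    """Attributions for each row of ``X`` (shape (B, d) or (d,)).

    Exact for linear targets at any step count (the gradient is constant
    along the path); for smooth nonlinear targets the completeness residual
    shrinks as the step count M grows.
    """
    config = config or IGConfig()
    config.validate()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    B, d = X.shape
    m = np.zeros(d) if config.baseline is None else np.asarray(config.baseline, float)
    if m.shape != (d,):
        raise ValueError(f"baseline shape {m.shape} != input dimension ({d},)")
    diff = X - m
    grad_sum = np.zeros_like(X)
    M = config.steps
    for k in range(1, M + 1):
        pts = m + (k / M) * diff
        _, g = f_grad(pts)
        if not np.isfinite(g).all():
            raise FloatingPointError(f"non-finite gradient at step {k}/{M}")
        grad_sum += g
    out = diff * grad_sum / M
    return out if X.ndim == 2 else out[0]


def integrated_gradients_per_unit(
    model: TrainedModel, x: np.ndarray, config: IGConfig | None = None
) -> np.ndarray:
    """Per-bottleneck-unit attributions for a single input, shape
    (bottleneck, d); aggregate with e.g. sum of absolute values."""
    config = config or IGConfig()
    config.validate()
    x = np.asarray(x, dtype=float).ravel()
    d = x.size
    m = np.zeros(d) if config.baseline is None else np.asarray(config.baseline, float)
    diff = x - m
    M = config.steps
    jac_sum = np.zeros((model.spec.bottleneck, d))
    for k in range(1, M + 1):
        jac_sum += model.encoder_jacobian(m + (k / M) * diff)
    return diff[None, :] * jac_sum / M


def completeness_residual(
    attributions: np.ndarray, f_grad: TargetFn, x: np.ndarray, m: np.ndarray | None = None
) -> float:
    """|sum_i IG_i - (f(x) - f(m))|, the completeness-axiom gap.

    Zero for linear targets; shrinks toward zero with the Riemann step
    count for smooth targets, so it serves as a convergence diagnostic.
    """
    x = np.asarray(x, dtype=float).ravel()
    m = np.zeros_like(x) if m is None else np.asarray(m, float).ravel()
    fx, _ = f_grad(x[None, :])
    fm, _ = f_grad(m[None, :])
    return float(abs(np.sum(attributions) - (fx[0] - fm[0])))


def attribute_cohort(
    model_set: GroupModelSet,
    edge_tables: dict[str, EdgeTable],
    group_labels: np.ndarray,
    config: IGConfig | None = None,
) -> AttributionMatrix:
    """Integrated gradients for every subject under their group's models.

    Each subject's residualized edge vector is mapped through the scaler of
    each split repeat's model (evaluation mode, dropout off), attributed
    against that repeat's encoder, and the attributions are averaged across
    repeats. Left/right hemisphere attributions are concatenated into one
    edge axis.
    """
    config = config or IGConfig()
    group_labels = np.asarray(group_labels)
    hemis = list(edge_tables)
    some_table = edge_tables[hemis[0]]
    n = some_table.n_subjects
    blocks = []
    for hemi in hemis:
        table = edge_tables[hemi]
        acc = np.zeros((n, table.n_edges))
        for g in model_set.groups:
            g_rows = np.flatnonzero(group_labels == g)
            if (g, hemi) not in model_set.models:
                raise KeyError(f"no model for group '{g}', hemisphere '{hemi}'")
            repeats = model_set.models[(g, hemi)]
            for model in repeats:
                scaled = model.scaler.transform(table.values[g_rows])
                ig = integrated_gradients(
                    encoder_target(model, config.aggregation if config.aggregation != "per_unit" else "sum"),
                    scaled,
                    config,
                )
                acc[g_rows] += ig / len(repeats)
        blocks.append(acc)
    values = np.hstack(blocks)
    edge_index = np.vstack([edge_tables[h].edge_index for h in hemis])
    return AttributionMatrix(
        values=values,
        subjects=list(some_table.subjects),
        edge_index=edge_index,
        normalization="raw",
        config=config,
    )


def znormalize(attr: AttributionMatrix) -> AttributionMatrix:
    """Z-score each edge across subjects, pooled over both groups.

    Zero-SD edges are set to 0 with a warning.
    """
    v = attr.values
    mean = v.mean(axis=0)
    sd = v.std(axis=0)
    zero = sd <= 1e-12 * np.maximum(1.0, np.abs(mean))
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-SD edges set to 0 in z-normalization")
    z = np.where(zero, 0.0, (v - mean) / np.where(zero, 1.0, sd))
    return AttributionMatrix(
        values=z,
        subjects=list(attr.subjects),
        edge_index=attr.edge_index,
        normalization="z",
        config=attr.config,
    )
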
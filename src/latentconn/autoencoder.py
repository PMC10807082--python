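"""Tanh autoencoder for edge vectors, trained with averaged SGD.

The model is a fully connected encoder-decoder: the encoder maps the input
edge vector x through tanh layers to a bottleneck code z = E(x), the
decoder mirrors the encoder sizes in reverse to produce y = D(z), and the
loss is the per-sample mean squared error L(x, y) = sum_i |x_i - y_i|^2 / n
averaged over the batch. Training uses averaged stochastic gradient descent
(gradient steps with tail averaging of the weights, a la Polyak-Ruppert)
with dropout on the input layer only; the epoch minimizing validation loss
is selected for evaluation, with dropout disabled.

Everything is plain numpy with hand-written backpropagation: cohorts are
small, layers are dense, and full determinism from a seed is required.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from latentconn.data import EdgeScaler, EdgeTable

Params = list[tuple[np.ndarray, np.ndarray]]


@dataclass
class EncoderSpec:
    """Architecture and training hyperparameters.

    Defaults follow the full-scale analysis (four encoder layers of
    7700/5500/2930/900 units, bottleneck 200, input dropout 0.3, learning
    rate 8e-5, 500 epochs of averaged SGD); every field is overridable, and
    small problems should use proportionally small layers.
    """

    hidden_sizes: list[int] = field(default_factory=lambda: [7700, 5500, 2930, 900])
    bottleneck: int = 200
    input_dropout: float = 0.3
    learning_rate: float = 0.00008
    max_epochs: int = 500
    optimizer: str = "asgd"  # "asgd" (tail-averaged) or "sgd"
    avg_start: float = 0.5  # fraction of epochs before averaging begins
    batch_size: int | None = None  # None = full batch

    def validate(self) -> None:
        if any(h <= 0 for h in self.hidden_sizes) or self.bottleneck <= 0:
            raise ValueError("all layer sizes must be positive")
        if not 0 <= self.input_dropout < 1:
            raise ValueError("input_dropout must be in [0, 1)")
        if self.optimizer not in ("asgd", "sgd"):
            raise ValueError(f"unknown optimizer '{self.optimizer}'")

    def layer_sizes(self, input_dim: int) -> list[int]:
        """Full layer-size chain; decoder mirrors encoder sizes in reverse."""
        return (
            [input_dim]
            + list(self.hidden_sizes)
            + [self.bottleneck]
            + list(reversed(self.hidden_sizes))
            + [input_dim]
        )


@dataclass
class SplitPlan:
    """One train/validation/test partition of a group's subjects."""

    repeat_id: int
    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    seed: int

    def validate(self, n_subjects: int) -> None:
        all_idx = np.concatenate([self.train, self.validation, self.test])
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("split partitions overlap")
        if sorted(all_idx) != list(range(n_subjects)):
            raise ValueError("split partitions are not exhaustive")


def make_splits(
    n_subjects: int,
    counts: tuple[int, int, int] | None = None,
    fractions: tuple[float, float, float] = (0.55, 0.25, 0.20),
    n_repeats: int = 100,
    seed: int = 0,
) -> list[SplitPlan]:
    """Random disjoint, exhaustive train/validation/test partitions.

    Explicit ``counts`` must sum exactly to ``n_subjects``; with
    ``fractions`` the remainder after rounding goes to training.
    """
    if counts is None:
        n_val = int(round(fractions[1] * n_subjects))
        n_test = int(round(fractions[2] * n_subjects))
        n_train = n_subjects - n_val - n_test
        counts = (n_train, n_val, n_test)
    if any(c < 1 for c in counts):
        raise ValueError(f"each partition needs >= 1 subject, got {counts}")
    if sum(counts) != n_subjects:
        raise ValueError(
            f"counts {counts} must sum to the group size {n_subjects}"
        )
    seeds = np.random.SeedSequence(seed).spawn(n_repeats)
    plans = []
    for r, ss in enumerate(seeds):
        sub_seed = int(ss.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(sub_seed)
        perm = rng.permutation(n_subjects)
        a, b = counts[0], counts[0] + counts[1]
        plans.append(
            SplitPlan(
                repeat_id=r,
                train=np.sort(perm[:a]),
                validation=np.sort(perm[a:b]),
                test=np.sort(perm[b:]),
                seed=sub_seed,
            )
        )
    return plans


def _init_params(sizes: list[int], rng: np.random.Generator) -> Params:
    """Symmetric uniform init scaled by layer fan-in."""
    params = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        bound = 1.0 / np.sqrt(fan_in)
        W = rng.uniform(-bound, bound, size=(fan_in, fan_out))
        b = np.zeros(fan_out)
        params.append((W, b))
    return params


def _forward(X: np.ndarray, params: Params) -> list[np.ndarray]:
    """Activations after each tanh layer (input excluded)."""
    acts = []
    a = X
    for W, b in params:
        a = np.tanh(a @ W + b)
        acts.append(a)
    return acts


def mse_loss(x: np.ndarray, y: np.ndarray) -> float:
    """Per-sample mean squared error, averaged over the batch.

    For a single pair of vectors this is sum_i (x_i - y_i)^2 / n.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return float(np.mean((x - y) ** 2, axis=1).mean())


@dataclass
class TrainedModel:
    """Selected weights plus the training record.

    ``params`` are the weights at ``selected_epoch`` (minimum validation
    loss, earliest on ties); ``n_encoder_layers`` marks where the encoder
    ends (the bottleneck activation). The per-edge input scaler used in
    training is attached so new subjects can be mapped to model space.
    """

    spec: EncoderSpec
    params: Params
    input_dim: int
    loss_trace: np.ndarray  # (max_epochs, 2): train, validation
    selected_epoch: int
    scaler: EdgeScaler | None = None

    @property
    def n_encoder_layers(self) -> int:
        return len(self.spec.hidden_sizes) + 1

    def _check_dim(self, X: np.ndarray, dim: int, what: str) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != dim:
            raise ValueError(f"{what} dimension {X.shape[1]} != expected {dim}")
        return X

    def encode(self, X: np.ndarray) -> np.ndarray:
        """Bottleneck code z = E(x); values in (-1, 1)."""
        X = self._check_dim(X, self.input_dim, "input")
        acts = _forward(X, self.params[: self.n_encoder_layers])
        return acts[-1]

    def decode(self, Z: np.ndarray) -> np.ndarray:
        Z = self._check_dim(Z, self.spec.bottleneck, "code")
        acts = _forward(Z, self.params[self.n_encoder_layers :])
        return acts[-1]

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return self.decode(self.encode(X))

    def encoder_value_and_grad(
        self, X: np.ndarray, aggregation: str = "sum"
    ) -> tuple[np.ndarray, np.ndarray]:
        """Scalarized encoder output f(x) and its input gradient.

        ``aggregation``: "sum" or "mean" over bottleneck units. Returns
        (values of shape (B,), gradients of shape (B, input_dim)).
        """
        X = self._check_dim(X, self.input_dim, "input")
        enc = self.params[: self.n_encoder_layers]
        acts = _forward(X, enc)
        z = acts[-1]
        if aggregation == "sum":
            values = z.sum(axis=1)
            g = np.ones_like(z)
        elif aggregation == "mean":
            values = z.mean(axis=1)
            g = np.full_like(z, 1.0 / z.shape[1])
        else:
            raise ValueError(f"unknown aggregation '{aggregation}'")
        for (W, _), a in zip(reversed(enc), reversed(acts)):
            g = (g * (1.0 - a**2)) @ W.T
        return values, g

    def encoder_jacobian(self, x: np.ndarray) -> np.ndarray:
        """Jacobian dz/dx of the bottleneck w.r.t. one input vector,
        shape (bottleneck, input_dim)."""
        x = self._check_dim(x, self.input_dim, "input")
        enc = self.params[: self.n_encoder_layers]
        acts = _forward(x, enc)
        G = np.eye(self.spec.bottleneck)
        for (W, _), a in zip(reversed(enc), reversed(acts)):
            G = (G * (1.0 - a**2)) @ W.T
        return G


def _backprop(X: np.ndarray, target: np.ndarray, params: Params) -> tuple[float, list]:
    """Loss and parameter gradients for one (possibly dropped-out) batch."""
    acts = _forward(X, params)
    y = acts[-1]
    B, n_feat = y.shape
    loss = float(np.mean((target - y) ** 2, axis=1).mean())
    grads = [None] * len(params)
    G = 2.0 * (y - target) / (n_feat * B)
    inputs = [X] + acts[:-1]
    for layer in range(len(params) - 1, -1, -1):
        a = acts[layer]
        delta = G * (1.0 - a**2)
        grads[layer] = (inputs[layer].T @ delta, delta.sum(axis=0))
        G = delta @ params[layer][0].T
    return loss, grads


def train(
    train_values: np.ndarray,
    val_values: np.ndarray,
    spec: EncoderSpec,
    seed: int = 0,
    scaler: EdgeScaler | None = None,
) -> TrainedModel:
    """Train an autoencoder and select the best-validation epoch.

    Inputs are expected pre-scaled to a tanh-compatible range ([-1, 1]).
    Dropout (rate ``spec.input_dropout``) is applied to the input layer
    during training only; per-epoch train/validation losses are recorded
    in evaluation mode, using the averaged weights once averaging begins.
    """
    spec.validate()
    train_values = np.asarray(train_values, dtype=float)
    val_values = np.asarray(val_values, dtype=float)
    input_dim = train_values.shape[1]
    sizes = spec.layer_sizes(input_dim)
    rng = np.random.default_rng(seed)
    params = _init_params(sizes, rng)

    averaging = spec.optimizer == "asgd"
    avg_from = int(np.floor(spec.avg_start * spec.max_epochs)) if averaging else None
    avg_params: Params | None = None
    n_avg = 0

    n_train = train_values.shape[0]
    batch = spec.batch_size or n_train
    keep = 1.0 - spec.input_dropout

    trace = np.empty((spec.max_epochs, 2))
    best_val = np.inf
    best_epoch = -1
    best_params: Params | None = None

    for epoch in range(spec.max_epochs):
        order = rng.permutation(n_train)
        for start in range(0, n_train, batch):
            idx = order[start : start + batch]
            Xb = train_values[idx]
            if spec.input_dropout > 0:
                mask = rng.random(Xb.shape) < keep
                Xin = Xb * mask / keep  # inverted dropout
            else:
                Xin = Xb
            loss, grads = _backprop(Xin, Xb, params)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    "reduce the learning rate"
                )
            params = [
                (W - spec.learning_rate * gW, b - spec.learning_rate * gb)
                for (W, b), (gW, gb) in zip(params, grads)
            ]
        if averaging and epoch >= avg_from:
            n_avg += 1
            if avg_params is None:
                avg_params = [(W.copy(), b.copy()) for W, b in params]
            else:
                avg_params = [
                    (aW + (W - aW) / n_avg, ab + (b - ab) / n_avg)
                    for (aW, ab), (W, b) in zip(avg_params, params)
                ]
        eff = avg_params if (averaging and avg_params is not None) else params
        y_tr = _forward(train_values, eff)[-1]
        y_va = _forward(val_values, eff)[-1]
        trace[epoch, 0] = mse_loss(train_values, y_tr)
        trace[epoch, 1] = mse_loss(val_values, y_va)
        if trace[epoch, 1] < best_val:  # strict: earliest epoch wins ties
            best_val = trace[epoch, 1]
            best_epoch = epoch
            best_params = [(W.copy(), b.copy()) for W, b in eff]

    return TrainedModel(
        spec=spec,
        params=best_params,
        input_dim=input_dim,
        loss_trace=trace,
        selected_epoch=best_epoch,
        scaler=scaler,
    )


def evaluate_reconstruction(
    model: TrainedModel, test_values: np.ndarray
) -> tuple[np.ndarray, tuple[float, float]]:
    """Per-subject Pearson r between input and reconstruction.

    Zero-variance inputs give an undefined r, reported as NaN with a
    warning; the summary (mean, SD) ignores missing values.
    """
    test_values = np.atleast_2d(np.asarray(test_values, dtype=float))
    recon = model.reconstruct(test_values)
    rs = np.empty(test_values.shape[0])
    for i in range(test_values.shape[0]):
        x, y = test_values[i], recon[i]
        if x.std() == 0 or y.std() == 0:
            warnings.warn(f"subject {i}: zero-variance vector, r undefined")
            rs[i] = np.nan
        else:
            rs[i] = np.corrcoef(x, y)[0, 1]
    valid = rs[~np.isnan(rs)]
    if valid.size == 0:
        return rs, (float("nan"), float("nan"))
    return rs, (float(valid.mean()), float(valid.std()))


@dataclass
class GroupModelSet:
    """Per-(group, hemisphere) models across split repeats."""

    models: dict[tuple[str, str], list[TrainedModel]]
    splits: dict[str, list[SplitPlan]]
    groups: tuple[str, ...]
    hemispheres: tuple[str, ...] = ("L", "R")


def train_group_models(
    edge_tables: dict[str, EdgeTable],
    group_labels: np.ndarray,
    spec: EncoderSpec,
    counts: dict[str, tuple[int, int, int]] | None = None,
    n_repeats: int = 1,
    seed: int = 0,
) -> GroupModelSet:
    """Train one autoencoder per group, hemisphere and split repeat.

    ``edge_tables`` maps hemisphere ("L"/"R") to the residualized
    EdgeTable covering all subjects; ``group_labels`` aligns with the
    table rows. Each group gets its own split plans (counts per group or
    the default 55/25/20 fractions). Two things are deliberately shared
    between the groups within a split repeat so that their attribution
    fields are comparable: the per-edge [-1, 1] scaler (fit on the union
    of both groups' training subjects — per-group scaling would silently
    absorb group mean differences) and the weight initialization (models
    start from identical weights and diverge only through their group's
    data, so attribution differences reflect the data rather than
    initialization luck).
    """
    group_labels = np.asarray(group_labels)
    groups = tuple(dict.fromkeys(group_labels))  # preserve order
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    master = np.random.SeedSequence(seed)
    split_seeds = {g: s for g, s in zip(groups, master.spawn(len(groups)))}
    splits: dict[str, list[SplitPlan]] = {}
    for g in groups:
        n_g = int((group_labels == g).sum())
        c = counts.get(g) if counts else None
        splits[g] = make_splits(
            n_g,
            counts=c,
            n_repeats=n_repeats,
            seed=int(split_seeds[g].generate_state(1)[0] % (2**31)),
        )
    group_rows = {g: np.flatnonzero(group_labels == g) for g in groups}
    # scaler and training seed shared across groups per (hemisphere, repeat)
    scalers: dict[tuple[str, int], EdgeScaler] = {}
    train_seeds: dict[tuple[str, int], int] = {}
    train_seed_root = master.spawn(1)[0]
    for hemi, table in edge_tables.items():
        for r in range(n_repeats):
            rows = np.concatenate(
                [group_rows[g][splits[g][r].train] for g in groups]
            )
            scalers[(hemi, r)] = EdgeScaler().fit(table.values[rows])
            train_seeds[(hemi, r)] = int(
                train_seed_root.spawn(1)[0].generate_state(1)[0] % (2**31)
            )
    models: dict[tuple[str, str], list[TrainedModel]] = {}
    for g in groups:
        g_rows = group_rows[g]
        for hemi, table in edge_tables.items():
            per_repeat = []
            for r, plan in enumerate(splits[g]):
                scaler = scalers[(hemi, r)]
                tr = scaler.transform(table.values[g_rows[plan.train]])
                va = scaler.transform(table.values[g_rows[plan.validation]])
                model = train(
                    tr, va, spec, seed=train_seeds[(hemi, r)], scaler=scaler
                )
                per_repeat.append(model)
            models[(g, hemi)] = per_repeat
    return GroupModelSet(
        models=models, splits=splits, groups=groups, hemispheres=tuple(edge_tables)
    )


def evaluate_group_models(
    model_set: GroupModelSet,
    edge_tables: dict[str, EdgeTable],
    group_labels: np.ndarray,
) -> dict[str, tuple[float, float]]:
    """Mean +/- SD test reconstruction r per group, pooled over
    hemispheres and split repeats."""
    group_labels = np.asarray(group_labels)
    out = {}
    for g in model_set.groups:
        g_rows = np.flatnonzero(group_labels == g)
        rs = []
        for hemi in model_set.hemispheres:
            table = edge_tables[hemi]
            for model, plan in zip(model_set.models[(g, hemi)], model_set.splits[g]):
                te = table.values[g_rows[plan.test]]
                r, _ = evaluate_reconstruction(model, model.scaler.transform(te))
                rs.append(r)
        rs = np.concatenate(rs)
        out[g] = (float(np.nanmean(rs)), float(np.nanstd(rs)))
    return out
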
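"""Connectivity data containers: parcel scheme, matrices, edge tables.

Connectivity is a symmetric nonnegative parcel-by-parcel matrix of
log-transformed streamline weights over a parcellation whose parcels carry a
hemisphere (L/R) and one of seven functional communities. Analysis operates
on the within-hemisphere upper-triangle edge vectors; inter-hemispheric
entries are discarded at the hemisphere split.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The seven intrinsic functional communities used for block summaries.
NETWORKS = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "frontoparietal",
    "default_mode",
)

HEMISPHERES = ("L", "R")


class ParcelScheme:
    """Assignment of each parcel to a hemisphere and a functional community.

    Parameters
    ----------
    table:
        DataFrame with columns ``parcel_id`` (0-based, contiguous),
        ``hemisphere`` (``L``/``R``) and ``network`` (one of :data:`NETWORKS`).
    """

    def __init__(self, table: pd.DataFrame):
        required = {"parcel_id", "hemisphere", "network"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"parcel scheme missing columns: {sorted(missing)}")
        table = table.sort_values("parcel_id").reset_index(drop=True)
        if not np.array_equal(table["parcel_id"].to_numpy(), np.arange(len(table))):
            raise ValueError("parcel_id must be 0-based and contiguous")
        bad_hemi = set(table["hemisphere"]) - set(HEMISPHERES)
        if bad_hemi:
            raise ValueError(f"unknown hemisphere labels: {sorted(bad_hemi)}")
        bad_net = set(table["network"]) - set(NETWORKS)
        if bad_net:
            raise ValueError(f"unknown network labels: {sorted(bad_net)}")
        self.table = table

    @property
    def n_parcels(self) -> int:
        return len(self.table)

    def hemisphere_parcels(self, hemisphere: str) -> np.ndarray:
        """Global parcel ids belonging to one hemisphere, ascending."""
        if hemisphere not in HEMISPHERES:
            raise ValueError(f"hemisphere must be one of {HEMISPHERES}")
        mask = self.table["hemisphere"] == hemisphere
        return self.table.loc[mask, "parcel_id"].to_numpy()

    @property
    def networks(self) -> np.ndarray:
        return self.table["network"].to_numpy()

    @classmethod
    def default(cls, n_parcels: int = 200) -> "ParcelScheme":
        """Balanced scheme: parcels split 50/50 L/R, communities in
        contiguous, near-equal blocks within each hemisphere (mirroring the
        layout of the 200-parcel scheme with 7 communities)."""
        if n_parcels % 2 != 0:
            raise ValueError("n_parcels must be even (equal hemispheres)")
        per_hemi = n_parcels // 2
        if per_hemi < len(NETWORKS):
            raise ValueError(
                f"need at least {len(NETWORKS)} parcels per hemisphere, got {per_hemi}"
            )
        rows = []
        for h, hemi in enumerate(HEMISPHERES):
            bounds = np.linspace(0, per_hemi, len(NETWORKS) + 1).astype(int)
            for k, net in enumerate(NETWORKS):
                for local in range(bounds[k], bounds[k + 1]):
                    rows.append((h * per_hemi + local, hemi, net))
        return cls(pd.DataFrame(rows, columns=["parcel_id", "hemisphere", "network"]))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ParcelScheme":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class ConnectivityMatrix:
    """One subject's symmetric nonnegative parcel-by-parcel weight matrix."""

    subject_id: str
    values: np.ndarray

    def validate(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"{self.subject_id}: matrix must be square, got {v.shape}")
        if not np.isfinite(v).all():
            bad = np.argwhere(~np.isfinite(v))
            raise ValueError(
                f"{self.subject_id}: non-finite entries at cells "
                f"{[(int(i), int(j)) for i, j in bad[:5]]}"
            )
        if not np.allclose(v, v.T):
            raise ValueError(f"{self.subject_id}: matrix not symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError(f"{self.subject_id}: diagonal not zero")


@dataclass
class EdgeTable:
    """Subjects-by-edges matrix with a map back to parcel pairs.

    ``edge_index`` holds (parcel_i, parcel_j) global ids with i < j; for a
    single hemisphere all pairs are intra-hemispheric. ``hemisphere`` is
    ``"L"``, ``"R"`` or ``"LR"`` (left block then right block on the edge
    axis).
    """

    values: np.ndarray
    subjects: list[str]
    edge_index: np.ndarray  # (n_edges, 2)
    hemisphere: str

    def __post_init__(self):
        if self.values.shape != (len(self.subjects), len(self.edge_index)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.subjects)} subjects x {len(self.edge_index)} edges"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_edges(self) -> int:
        return len(self.edge_index)

    def subset(self, rows: Sequence[int]) -> "EdgeTable":
        rows = np.asarray(rows)
        return EdgeTable(
            self.values[rows],
            [self.subjects[i] for i in rows],
            self.edge_index,
            self.hemisphere,
        )

    def edge_networks(self, scheme: ParcelScheme) -> np.ndarray:
        """Unordered (network_a, network_b) block label per edge."""
        nets = scheme.networks
        pairs = np.array(
            [tuple(sorted((nets[i], nets[j]))) for i, j in self.edge_index],
            dtype=object,
        )
        return pairs

    def to_tsv(self, path: str | Path) -> None:
        cols = [f"e{i}_{j}" for i, j in self.edge_index]
        pd.DataFrame(self.values, index=self.subjects, columns=cols).to_csv(
            path, sep="\t", index_label="subject_id"
        )


def triu_indices(p: int) -> np.ndarray:
    """Row-major upper-triangle pairs (i, j), i < j, diagonal excluded."""
    iu = np.triu_indices(p, k=1)
    return np.column_stack(iu)


def vectorize(matrix: np.ndarray) -> np.ndarray:
    """Upper triangle (i < j) of a square symmetric matrix, row-major."""
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"expected square matrix, got shape {m.shape}")
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def devectorize(vector: np.ndarray, n_parcels: int) -> np.ndarray:
    """Inverse of :func:`vectorize`: symmetric matrix with zero diagonal."""
    vector = np.asarray(vector)
    expected = n_parcels * (n_parcels - 1) // 2
    if vector.shape[-1] != expected:
        raise ValueError(
            f"vector length {vector.shape[-1]} does not match "
            f"{n_parcels} parcels ({expected} edges)"
        )
    out = np.zeros((n_parcels, n_parcels), dtype=vector.dtype)
    iu = np.triu_indices(n_parcels, k=1)
    out[iu] = vector
    out += out.T
    return out


def load_connectivity(
    paths: Iterable[str | Path], scheme: ParcelScheme
) -> list[ConnectivityMatrix]:
    """Read dense TSV matrices (one file per subject; filename stem = id).

    Asymmetric inputs are symmetrized as (M + Mᵀ)/2 with a logged warning;
    wrong dimensions or non-finite cells raise a load error naming the file.
    """
    out = []
    for path in paths:
        path = Path(path)
        values = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)
        if values.shape != (scheme.n_parcels, scheme.n_parcels):
            raise ValueError(
                f"{path}: expected {scheme.n_parcels}x{scheme.n_parcels} "
                f"matrix, got {values.shape[0]}x{values.shape[1]}"
            )
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))
            raise ValueError(
                f"{path}: non-finite entries at cells {[(int(i), int(j)) for i, j in bad[:5]]}"
            )
        if not np.allclose(values, values.T):
            logger.warning("%s: asymmetric input symmetrized as (M + M^T)/2", path)
            values = (values + values.T) / 2.0
        np.fill_diagonal(values, 0.0)
        out.append(ConnectivityMatrix(subject_id=path.stem, values=values))
    return out


def split_hemispheres(
    matrix: ConnectivityMatrix | np.ndarray, scheme: ParcelScheme
) -> tuple[np.ndarray, np.ndarray]:
    """Within-hemisphere submatrices (left, right); inter-hemispheric
    entries are discarded."""
    values = matrix.values if isinstance(matrix, ConnectivityMatrix) else matrix
    left = scheme.hemisphere_parcels("L")
    right = scheme.hemisphere_parcels("R")
    if len(left) != len(right):
        raise ValueError(
            f"unbalanced hemispheres: {len(left)} left vs {len(right)} right parcels"
        )
    return values[np.ix_(left, left)], values[np.ix_(right, right)]


def build_edge_table(
    matrices: Sequence[ConnectivityMatrix], scheme: ParcelScheme, hemisphere: str
) -> EdgeTable:
    """Vectorize one hemisphere of every subject into an EdgeTable."""
    parcels = scheme.hemisphere_parcels(hemisphere)
    local_pairs = triu_indices(len(parcels))
    edge_index = parcels[local_pairs]
    rows = []
    for m in matrices:
        sub = m.values[np.ix_(parcels, parcels)]
        rows.append(vectorize(sub))
    return EdgeTable(
        np.asarray(rows), [m.subject_id for m in matrices], edge_index, hemisphere
    )


def concat_hemispheres(left: EdgeTable, right: EdgeTable) -> EdgeTable:
    """Concatenate left and right edge tables along the edge axis."""
    if left.subjects != right.subjects:
        raise ValueError("left/right tables cover different subjects")
    return EdgeTable(
        np.hstack([left.values, right.values]),
        left.subjects,
        np.vstack([left.edge_index, right.edge_index]),
        "LR",
    )


def _confound_design(phenotype: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Design matrix [intercept, age, sex, site dummies] in phenotype row
    order. Collinear columns are dropped with a warning."""
    n = len(phenotype)
    cols = [np.ones(n)]
    names = ["intercept"]
    cols.append(phenotype["age"].to_numpy(dtype=float))
    names.append("age")
    sex = phenotype["sex"]
    if sex.dtype == object:
        sex = (sex == sex.iloc[0]).astype(float)  # arbitrary reference level
    cols.append(sex.to_numpy(dtype=float))
    names.append("sex")
    site_dummies = pd.get_dummies(phenotype["site"], prefix="site", drop_first=True)
    for c in site_dummies.columns:
        cols.append(site_dummies[c].to_numpy(dtype=float))
        names.append(c)
    X = np.column_stack(cols)
    # drop collinear columns (rank-deficient design, e.g. single site)
    keep = [0]
    for j in range(1, X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) > len(keep):
            keep.append(j)
        else:
            warnings.warn(
                f"dropping collinear confound column '{names[j]}'", stacklevel=3
            )
    return X[:, keep], [names[j] for j in keep]


def residualize_confounds(edge_table: EdgeTable, phenotype: pd.DataFrame) -> EdgeTable:
    """OLS residuals of every edge on [intercept, age, sex, site dummies].

    The regression is fit on all subjects pooled across groups so that group
    signal does not leak into confound estimates. Residuals have zero mean
    and zero sample correlation with each covariate per edge.
    """
    pheno = phenotype.set_index("subject_id").loc[edge_table.subjects].reset_index()
    if len(pheno) != edge_table.n_subjects:
        raise ValueError("phenotype table does not cover all subjects")
    X, _ = _confound_design(pheno)
    Y = edge_table.values
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return EdgeTable(resid, list(edge_table.subjects), edge_table.edge_index, edge_table.hemisphere)


class EdgeScaler:
    """Per-edge min-max rescaling to [-1, 1], frozen on the training set.

    The decoder's tanh output is bounded in (-1, 1); residualized edges are
    not, so each edge is linearly mapped so the training range spans
    [-1, 1]. Constant edges map to 0. Validation/test values outside the
    training range are left unclipped (the encoder input is unconstrained).
    """

    def __init__(self) -> None:
        self.lo: np.ndarray | None = None
        self.hi: np.ndarray | None = None

    def fit(self, values: np.ndarray) -> "EdgeScaler":
        self.lo = values.min(axis=0)
        self.hi = values.max(axis=0)
        return self

    def transform(self, values: np.ndarray) -> np.ndarray:
        if self.lo is None:
            raise RuntimeError("scaler not fitted")
        span = self.hi - self.lo
        safe = np.where(span == 0, 1.0, span)
        out = 2.0 * (values - self.lo) / safe - 1.0
        return np.where(span == 0, 0.0, out)

    def fit_transform(self, values: np.ndarray) -> np.ndarray:
        return self.fit(values).transform(values)
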
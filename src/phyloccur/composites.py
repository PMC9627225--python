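"""Principal-component composites: two trait axes and one environment axis.

Six trait variables (maximum height, midpoint leaf length and width, maximum
fruit size, maximum calyx length, maximum corolla length) are log-transformed,
z-scored, and reduced by SVD to two axes.  With the default orientation
anchors, axis 1 captures jointly increasing leaf and fruit size and axis 2 a
flower-size-versus-height contrast; the axis scores enter the occurrence
model as species-level covariates.

The environmental-stress axis is the first principal component of the three
z-scored (not logged) area variables — % ultramafic soil, minimum monthly
rainfall, % lowland — oriented so ultramafic cover loads positively, i.e.
larger scores mean more stressful areas (more ultramafic soil, drier dry
season, less lowland).

Conventions: natural log; sample (n-1) standard deviation; loadings are
unit-norm right singular vectors; each axis is sign-flipped so its anchor
variable loads positively, which makes the decomposition deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AreaTable, TraitTable

__all__ = [
    "PCAResult",
    "TraitScores",
    "AreaStress",
    "derive_six_traits",
    "log_zscore",
    "pca",
    "trait_axes",
    "stress_axis",
]

TRAIT_VARS = [
    "height_max",
    "leaf_length_mid",
    "leaf_width_mid",
    "fruit_size_max",
    "calyx_length_max",
    "corolla_length_max",
]

STRESS_VARS = ["ultramafic_pct", "rainfall_min", "lowland_pct"]


@dataclass(frozen=True)
class PCAResult:
    """SVD principal components with deterministic sign orientation.

    ``loadings`` is a variable-by-axis DataFrame of unit-norm eigenvector
    columns; ``scores`` the observation-by-axis projections of the
    standardized data; ``var_explained`` the fraction of total variance per
    retained axis; ``orientation_anchor`` the variable forced to load
    positively on each axis.
    """

    loadings: pd.DataFrame
    scores: pd.DataFrame
    var_explained: pd.Series
    orientation_anchor: dict[str, str]


@dataclass(frozen=True)
class TraitScores:
    """Per-species values of the two trait composite axes."""

    data: pd.DataFrame  # index species; columns pc1_leaf_fruit, pc2_flower_vs_height

    @property
    def species(self) -> list[str]:
        return list(self.data.index)


@dataclass(frozen=True)
class AreaStress:
    """Per-area environmental-stress score (mean zero across areas)."""

    data: pd.Series  # index area

    @property
    def areas(self) -> list[str]:
        return list(self.data.index)


def derive_six_traits(table: TraitTable) -> pd.DataFrame:
    """Collapse the raw measurements to the six analysis variables.

    Leaf length and width use range midpoints, (max + min) / 2; the other
    four traits are the recorded maxima.
    """
    df = table.data
    out = pd.DataFrame(index=df.index)
    out["height_max"] = df["height_max"]
    out["leaf_length_mid"] = (df["leaf_length_max"] + df["leaf_length_min"]) / 2
    out["leaf_width_mid"] = (df["leaf_width_max"] + df["leaf_width_min"]) / 2
    out["fruit_size_max"] = df["fruit_size_max"]
    out["calyx_length_max"] = df["calyx_length_max"]
    out["corolla_length_max"] = df["corolla_length_max"]
    return out


def log_zscore(matrix: pd.DataFrame) -> pd.DataFrame:
    """Natural-log transform then z-score each column (ddof=1).

    Raises ``ValueError`` for non-positive entries or a column that is
    constant after the log (zero variance makes the z-score undefined).
    """
    if (matrix <= 0).any().any():
        raise ValueError("log_zscore requires strictly positive entries")
    logged = np.log(matrix)
    sd = logged.std(axis=0, ddof=1)
    zero = sd.index[~(sd > 0)]
    if len(zero):
        raise ValueError(f"constant column(s) after log: {list(zero)}")
    return (logged - logged.mean(axis=0)) / sd


def zscore(matrix: pd.DataFrame) -> pd.DataFrame:
    """z-score each column without a log transform (ddof=1)."""
    sd = matrix.std(axis=0, ddof=1)
    zero = sd.index[~(sd > 0)]
    if len(zero):
        raise ValueError(f"constant column(s): {list(zero)}")
    return (matrix - matrix.mean(axis=0)) / sd


def pca(standardized: pd.DataFrame, k: int,
        anchors: dict[str, str] | None = None) -> PCAResult:
    """Principal components of already-standardized data via SVD.

    Axes are ordered by decreasing variance; ``var_explained`` comes from the
    squared singular values over all axes (so it sums to 1 across the full
    decomposition, not just the ``k`` retained).  ``anchors`` maps axis name
    (``"PC1"``, ...) to the variable whose loading is forced positive; axes
    without an anchor are oriented so their largest-magnitude loading is
    positive.
    """
    p = standardized.shape[1]
    if k > p:
        raise ValueError(f"k={k} exceeds number of variables ({p})")
    X = standardized.to_numpy(dtype=float)
    X = X - X.mean(axis=0)  # guard: z-scored input is already centered
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    total = float((s**2).sum())
    var_frac = s**2 / total
    axis_names = [f"PC{i + 1}" for i in range(k)]
    load = vt[:k].T.copy()  # variables x k, unit-norm columns
    anchors = dict(anchors or {})
    used_anchor: dict[str, str] = {}
    for j, name in enumerate(axis_names):
        var = anchors.get(name)
        if var is None:
            var = standardized.columns[int(np.argmax(np.abs(load[:, j])))]
        idx = standardized.columns.get_loc(var)
        if load[idx, j] < 0:
            load[:, j] = -load[:, j]
        used_anchor[name] = var
    loadings = pd.DataFrame(load, index=standardized.columns, columns=axis_names)
    scores = pd.DataFrame(X @ load, index=standardized.index, columns=axis_names)
    return PCAResult(
        loadings=loadings,
        scores=scores,
        var_explained=pd.Series(var_frac[:k], index=axis_names),
        orientation_anchor=used_anchor,
    )


def trait_axes(
    table: TraitTable,
    anchors: dict[str, str] | None = None,
) -> tuple[TraitScores, PCAResult]:
    """Two-axis trait PCA: derive_six_traits -> log_zscore -> pca(k=2).

    Default anchors orient axis 1 by midpoint leaf length (leaf/fruit size
    increases with the score) and axis 2 by maximum calyx length (flower size
    increases, height decreases).
    """
    if table.n_species < 3:
        raise ValueError("trait PCA needs at least 3 species")
    if anchors is None:
        anchors = {"PC1": "leaf_length_mid", "PC2": "calyx_length_max"}
    std = log_zscore(derive_six_traits(table))
    res = pca(std, k=2, anchors=anchors)
    scores = res.scores.rename(
        columns={"PC1": "pc1_leaf_fruit", "PC2": "pc2_flower_vs_height"}
    )
    return TraitScores(data=scores), res


def stress_axis(
    areas: AreaTable,
    anchors: dict[str, str] | None = None,
) -> tuple[AreaStress, PCAResult]:
    """One-axis environment PCA over the three z-scored stressor variables."""
    if anchors is None:
        anchors = {"PC1": "ultramafic_pct"}
    std = zscore(areas.data[STRESS_VARS])
    res = pca(std, k=1, anchors=anchors)
    return AreaStress(data=res.scores["PC1"].rename("stress")), res
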
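"""PCA on gene subsets, factor overlays, quadrant tests, and clustering.

PCA treats samples as observations and a chosen gene subset (differentially
expressed genes, or stage-correlated genes) as variables, on per-gene scaled
values. Sign indeterminacy is resolved deterministically: each dimension is
oriented so its largest-magnitude gene loading is positive, which makes
coordinates reproducible across linear-algebra backends; a helper can
re-orient a dimension so the normal condition's mean coordinate is positive,
matching the plotting convention of condition overlays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .datamodel import ValidationError
from .preprocess import ScaledMatrix


@dataclass
class PCAResult:
    """Sample coordinates, variance fractions and loadings of one PCA."""

    coordinates: pd.DataFrame      # samples x dimensions ("Dim1", ...)
    variance_fraction: np.ndarray  # per dimension, non-increasing
    loadings: pd.DataFrame         # genes x dimensions, orthonormal columns
    subset: str = ""               # description of the gene subset / tissue

    @property
    def n_dim(self) -> int:
        return self.coordinates.shape[1]


def pca(scaled: ScaledMatrix | pd.DataFrame, gene_subset=None,
        n_dim: int | None = None, subset_label: str = "") -> PCAResult:
    """Principal components of samples over a gene subset.

    Input is genes x samples (scaled values); the decomposition is an SVD of
    the column-centered samples x genes matrix. Variance fractions are
    squared singular values over their total.
    """
    values = scaled.values if isinstance(scaled, ScaledMatrix) else scaled
    if gene_subset is not None:
        gene_subset = [g for g in gene_subset if g in values.index]
        values = values.loc[gene_subset]
    if values.shape[0] < 2:
        raise ValidationError("pca needs at least 2 genes in the subset")
    if values.shape[1] < 2:
        raise ValidationError("pca needs at least 2 samples")
    X = values.to_numpy(float).T          # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total = (s ** 2).sum()
    frac = s ** 2 / total if total > 0 else np.zeros_like(s)
    # orient: largest-|loading| gene positive per dimension
    flip = np.ones(len(s))
    for d in range(len(s)):
        j = int(np.argmax(np.abs(Vt[d])))
        if Vt[d, j] < 0:
            flip[d] = -1.0
    U = U * flip[None, :]
    Vt = Vt * flip[:, None]
    coords = U * s[None, :]
    if n_dim is not None:
        coords, frac, Vt = coords[:, :n_dim], frac[:n_dim], Vt[:n_dim]
    dims = [f"Dim{d + 1}" for d in range(coords.shape[1])]
    return PCAResult(
        coordinates=pd.DataFrame(coords, index=values.columns, columns=dims),
        variance_fraction=frac,
        loadings=pd.DataFrame(Vt.T, index=values.index, columns=dims),
        subset=subset_label)


def orient_dimension(result: PCAResult, meta: pd.DataFrame, dim: int = 1,
                     positive_condition: str = "normal") -> PCAResult:
    """Flip one dimension so the given condition's mean coordinate is positive."""
    col = f"Dim{dim}"
    cond = meta.set_index("sample_id").loc[result.coordinates.index, "condition"]
    if result.coordinates.loc[(cond == positive_condition).to_numpy(), col].mean() < 0:
        coords = result.coordinates.copy()
        loadings = result.loadings.copy()
        coords[col] = -coords[col]
        loadings[col] = -loadings[col]
        return PCAResult(coords, result.variance_fraction, loadings,
                         result.subset)
    return result


@dataclass
class QuadrantTable:
    """Condition x coordinate-sign 2x2 table with Fisher's exact test."""

    dim: int
    counts: pd.DataFrame  # rows: condition; columns: positive, negative
    odds_ratio: float
    pvalue: float

    def to_dict(self) -> dict:
        return {"dim": self.dim,
                "counts": {c: self.counts.loc[c].to_dict()
                           for c in self.counts.index},
                "odds_ratio": self.odds_ratio, "pvalue": self.pvalue}


def quadrant_classification(result: PCAResult, meta: pd.DataFrame,
                            dim: int = 2) -> QuadrantTable:
    """Cross-classify samples by condition and coordinate sign on one axis.

    Coordinates exactly at zero count as positive (the boundary belongs to
    the upper half-plane). Attaches the two-sided Fisher exact p.
    """
    col = f"Dim{dim}"
    cond = meta.set_index("sample_id").loc[result.coordinates.index, "condition"]
    pos = result.coordinates[col].to_numpy() >= 0
    table = pd.DataFrame(0, index=["diabetic", "normal"],
                         columns=["positive", "negative"])
    for c, p in zip(cond, pos):
        table.loc[c, "positive" if p else "negative"] += 1
    orr, p = fisher_exact_2x2(table.to_numpy())
    return QuadrantTable(dim=dim, counts=table, odds_ratio=orr, pvalue=p)


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test for a 2x2 table of nonnegative integers.

    The two-sided p sums the hypergeometric probabilities of all tables with
    the observed margins whose probability does not exceed the observed
    table's (the summed-probabilities convention). The odds ratio is the
    sample odds ratio a*d / (b*c), infinite when b*c = 0 with a*d > 0.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValidationError("fisher_exact_2x2 expects a 2x2 table")
    if (t < 0).any():
        raise ValidationError("table entries must be nonnegative")
    if not np.issubdtype(t.dtype, np.integer):
        if np.any(t % 1 != 0):
            raise ValidationError("table entries must be integers")
        t = t.astype(np.int64)
    if t.sum() == 0:
        raise ValidationError("all margins are zero")
    a, b, c, d = t.ravel()
    if b * c == 0:
        orr = np.inf if a * d > 0 else np.nan
    else:
        orr = a * d / (b * c)
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return float(orr), float(p)


def factor_association_scan(result: PCAResult, meta: pd.DataFrame,
                            factor: str, max_dim: int = 10,
                            n_permutations: int = 10_000,
                            seed: int = 0) -> pd.DataFrame:
    """Associate each dimension with a design factor, with permutation p.

    Binary factors (condition, sex) use the point-biserial correlation of
    the group indicator with the coordinates; the somite stage uses Spearman
    correlation. Permutation p-values shuffle the factor across samples with
    a seeded generator. Constant factors yield NaN.
    """
    meta_by_id = meta.set_index("sample_id")
    fvals = meta_by_id.loc[result.coordinates.index, factor]
    max_dim = min(max_dim, result.n_dim)
    coords = result.coordinates.iloc[:, :max_dim].to_numpy(float)
    if fvals.nunique() < 2:
        import warnings
        warnings.warn(f"factor {factor!r} is constant; associations are NaN",
                      stacklevel=2)
        return pd.DataFrame({"dim": np.arange(1, max_dim + 1),
                             "statistic": np.nan, "pvalue": np.nan})
    if factor == "somite_pairs":
        x = stats.rankdata(fvals.to_numpy(float))
        y = np.apply_along_axis(stats.rankdata, 0, coords)
    else:
        levels = sorted(fvals.unique())
        if len(levels) != 2:
            raise ValidationError(
                f"factor {factor!r} must be binary, got levels {levels}")
        x = (fvals == levels[1]).to_numpy(float)
        y = coords
    obs = _corr_with_columns(x, y)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(max_dim)
    for _ in range(n_permutations):
        perm = rng.permutation(x)
        exceed += np.abs(_corr_with_columns(perm, y)) >= np.abs(obs) - 1e-12
    pvals = (exceed + 1) / (n_permutations + 1)
    return pd.DataFrame({"dim": np.arange(1, max_dim + 1), "statistic": obs,
                         "pvalue": pvals})


def _corr_with_columns(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    xd = x - x.mean()
    Yd = Y - Y.mean(axis=0, keepdims=True)
    denom = np.sqrt((xd ** 2).sum() * (Yd ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xd @ Yd) / denom
    return np.where(denom > 0, r, np.nan)


@dataclass
class ClusterResult:
    """Leaf ordering and merge tree from agglomerative clustering."""

    labels: list[str]
    leaf_order: list[int]
    linkage_matrix: np.ndarray = field(repr=False)

    @property
    def ordered_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_order]


def hier_cluster(matrix: pd.DataFrame, axis: str = "genes",
                 distance: str = "one_minus_pearson",
                 linkage: str = "average") -> ClusterResult:
    """Agglomerative clustering of genes or samples.

    The default distance is 1 - Pearson correlation between profiles
    (centered); ``one_minus_uncentered`` uses the uncentered correlation
    instead. Ties in merge order resolve deterministically.
    """
    if axis not in ("genes", "samples"):
        raise ValueError(f"axis must be 'genes' or 'samples', got {axis!r}")
    values = matrix.to_numpy(float)
    labels = list(matrix.index if axis == "genes" else matrix.columns)
    if axis == "samples":
        values = values.T
    if values.shape[0] < 2:
        raise ValidationError("clustering needs at least 2 items")
    if np.isnan(values).any():
        raise ValidationError(
            "matrix contains NaN; impute or drop incomplete rows first")
    if distance == "one_minus_pearson":
        profiles = values - values.mean(axis=1, keepdims=True)
    elif distance == "one_minus_uncentered":
        profiles = values
    else:
        raise ValueError(f"unknown distance {distance!r}")
    norms = np.sqrt((profiles ** 2).sum(axis=1, keepdims=True))
    norms[norms == 0] = 1.0
    unit = profiles / norms
    corr = np.clip(unit @ unit.T, -1.0, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    order = hierarchy.leaves_list(Z)
    return ClusterResult(labels=labels, leaf_order=[int(i) for i in order],
                         linkage_matrix=Z)
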
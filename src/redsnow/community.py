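"""Red-vs-white-snow community comparisons on count tables.

Implements the multivariate toolkit used to contrast snow microbial
communities: common-depth normalization with a log transform,
Bray-Curtis dissimilarities, permutational multivariate ANOVA
(PERMANOVA) on the distance matrix, similarity-profile (SIMPROF)
pruning of an average-linkage dendrogram, principal component
analysis, and per-feature one-way ANOVA with Benjamini-Hochberg
adjustment. The permutation machinery, dissimilarity, PERMANOVA,
SIMPROF and PCA are implemented here directly; only the BH adjustment
is delegated to statsmodels.

Matrix orientation convention: count tables and normalized matrices
are features x samples (rows = taxa or pathways, columns = samples),
matching the on-disk TSV layout. Distances, ordination scores and
cluster labels are over samples.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.stats import f as f_dist
from statsmodels.stats.multitest import multipletests

from .errors import DataError, DimensionError, ParameterError


# ---------------------------------------------------------------------------
# containers


@dataclass
class CountTable:
    """Sample-by-feature read counts with a group label per sample."""

    counts: pd.DataFrame  # features x samples, nonnegative integers
    groups: pd.Series  # index = sample IDs, values = group labels

    def __post_init__(self) -> None:
        if self.counts.columns.duplicated().any():
            raise DataError("duplicate sample IDs in count table")
        if self.counts.index.duplicated().any():
            raise DataError("duplicate feature IDs in count table")
        missing = [s for s in self.counts.columns if s not in self.groups.index]
        if missing:
            raise DataError(f"samples missing a group label: {missing}")
        self.groups = self.groups.loc[self.counts.columns]
        values = self.counts.to_numpy()
        if not np.isfinite(values).all() or (values < 0).any():
            raise DataError("counts must be finite and nonnegative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def write_tsv(self, counts_path: str | Path, groups_path: str | Path) -> None:
        """Write the counts (features x samples) and the two-column group map."""
        self.counts.rename_axis("feature_id").to_csv(counts_path, sep="\t")
        self.groups.rename_axis("sample_id").to_csv(groups_path, sep="\t")

    @classmethod
    def read_tsv(
        cls, counts_path: str | Path, groups_path: str | Path
    ) -> "CountTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        groups = pd.read_csv(groups_path, sep="\t", index_col=0).iloc[:, 0]
        return cls(counts=counts, groups=groups)


@dataclass
class DistanceMatrix:
    """Square symmetric dissimilarity matrix over samples."""

    values: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise DimensionError("distance matrix shape does not match sample IDs")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise DataError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise DataError("distance matrix diagonal is not zero")

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]


# ---------------------------------------------------------------------------
# normalization and feature selection


def normalize_log(
    table: CountTable, method: str = "scale", seed: int | None = None
) -> pd.DataFrame:
    """Depth-normalize to the minimum sample total, then ln(x + 1).

    ``method="scale"`` (default) rescales every sample's counts by
    ``min_total / sample_total``, a deterministic common-depth
    normalization; ``method="rarefy"`` subsamples reads without
    replacement down to the minimum total (requires ``seed``). The
    natural log with pseudocount 1 preserves zeros.
    """
    counts = table.counts.astype(float)
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise DataError(f"samples with zero total counts: {list(zero.index)}")
    min_total = totals.min()
    if method == "scale":
        scaled = counts * (min_total / totals)
    elif method == "rarefy":
        rng = np.random.default_rng(seed)
        target = int(min_total)
        cols = {}
        for s in counts.columns:
            col = table.counts[s].to_numpy().astype(int)
            reads = np.repeat(np.arange(len(col)), col)
            keep = rng.choice(reads, size=target, replace=False)
            cols[s] = np.bincount(keep, minlength=len(col)).astype(float)
        scaled = pd.DataFrame(cols, index=counts.index)
    else:
        raise ParameterError(f"unknown normalization method {method!r}")
    return np.log1p(scaled)


def standardize_features(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-feature z-scoring across samples (optional, not a default step)."""
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return pd.DataFrame((values - mean) / sd, index=matrix.index, columns=matrix.columns)


def select_top_variable(matrix: pd.DataFrame, k: int) -> pd.DataFrame:
    """Keep the k features with largest variance across samples.

    Ties are broken by feature ID in lexicographic order so selection
    is deterministic.
    """
    if k <= 0:
        raise ParameterError("k must be positive")
    if k > len(matrix.index):
        raise ParameterError(f"k={k} exceeds the {len(matrix.index)} features")
    variances = matrix.var(axis=1, ddof=1)
    order = sorted(matrix.index, key=lambda f: (-variances[f], f))
    return matrix.loc[order[:k]]


# ---------------------------------------------------------------------------
# Bray-Curtis


def _bray_curtis_square(sample_matrix: np.ndarray) -> np.ndarray:
    """Pairwise Bray-Curtis over rows of a (samples x features) array."""
    x = sample_matrix[:, None, :]
    y = sample_matrix[None, :, :]
    num = np.abs(x - y).sum(axis=-1)
    den = (x + y).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    np.fill_diagonal(d, 0.0)
    return d


def bray_curtis(matrix: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples (columns).

    d(x, y) = sum|x_i - y_i| / sum(x_i + y_i); two all-zero samples are
    at distance 0 by convention. Entries must be nonnegative.
    """
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise DataError("Bray-Curtis requires nonnegative abundances")
    return DistanceMatrix(
        values=_bray_curtis_square(values.T), ids=list(matrix.columns)
    )


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    """Pseudo-F, permutation p-value and provenance of a PERMANOVA run."""

    statistic: float
    p_value: float
    n_permutations: int
    method: str  # "exhaustive" or "monte-carlo"
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "pseudo_F": self.statistic,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "method": self.method,
            "seed": self.seed,
        }


def _group_codes(groups) -> tuple[np.ndarray, list]:
    codes, uniques = pd.factorize(np.asarray(groups))
    return codes.astype(np.int64), list(uniques)


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Pseudo-F from squared distances and integer group codes.

    SS_total = sum_{i<j} d_ij^2 / N, SS_within sums the same quantity
    inside each group divided by the group size; SS_between is their
    difference.
    """
    n = len(codes)
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub.sum() / (2.0 * len(idx))
    ss_between = ss_total - ss_within
    df_between = n_groups - 1
    df_within = n - n_groups
    if ss_within <= 0:
        return math.inf if ss_between > 0 else 0.0
    return (ss_between / df_between) / (ss_within / df_within)


def _distinct_label_arrangements(codes: np.ndarray):
    """Yield every distinct assignment of the multiset of group labels."""
    n = len(codes)
    counts = np.bincount(codes)
    positions = list(range(n))

    def rec(remaining: tuple[int, ...], grp: int, out: np.ndarray):
        if grp == len(counts) - 1:
            out[list(remaining)] = grp
            yield out.copy()
            return
        for chosen in itertools.combinations(remaining, int(counts[grp])):
            out[list(chosen)] = grp
            rest = tuple(p for p in remaining if p not in chosen)
            yield from rec(rest, grp + 1, out)

    yield from rec(tuple(positions), 0, np.empty(n, dtype=np.int64))


def n_distinct_arrangements(codes: np.ndarray) -> int:
    counts = np.bincount(codes)
    total = math.factorial(len(codes))
    for c in counts:
        total //= math.factorial(int(c))
    return total


def permanova(
    dist: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    The pseudo-F compares between-group to within-group sums of squared
    dissimilarities. The p-value permutes group labels; when the number
    of distinct label arrangements is at most ``n_permutations`` the
    null distribution is enumerated exhaustively (p = fraction of
    arrangements with F at least the observed, the observed arrangement
    included), otherwise Monte-Carlo with the observed statistic added
    to numerator and denominator so p is never zero.
    """
    codes, uniques = _group_codes(groups)
    if len(codes) != len(dist.ids):
        raise DimensionError("group labels do not match distance matrix size")
    if len(uniques) < 2:
        raise DataError("PERMANOVA needs at least two groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        raise DataError("every group needs at least two samples")

    d2 = dist.values**2
    if not (d2 > 0).any():
        warnings.warn("all dissimilarities are zero; PERMANOVA is degenerate")
        return PermanovaResult(0.0, 1.0, 0, "degenerate", seed)

    f_obs = _pseudo_f(d2, codes, len(uniques))
    tol = 1e-12

    n_arrangements = n_distinct_arrangements(codes)
    if n_arrangements <= n_permutations:
        hits = 0
        for arrangement in _distinct_label_arrangements(codes):
            if _pseudo_f(d2, arrangement, len(uniques)) >= f_obs - tol:
                hits += 1
        return PermanovaResult(
            statistic=f_obs,
            p_value=hits / n_arrangements,
            n_permutations=n_arrangements,
            method="exhaustive",
            seed=seed,
        )

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        if _pseudo_f(d2, perm, len(uniques)) >= f_obs - tol:
            hits += 1
    return PermanovaResult(
        statistic=f_obs,
        p_value=(1 + hits) / (1 + n_permutations),
        n_permutations=n_permutations,
        method="monte-carlo",
        seed=seed,
    )


# ---------------------------------------------------------------------------
# SIMPROF clustering


@dataclass
class SimprofTest:
    """One similarity-profile test at a dendrogram node."""

    samples: list[str]
    pi: float
    p_value: float
    significant: bool


@dataclass
class SimprofResult:
    """Cluster assignment after similarity-profile pruning."""

    labels: pd.Series  # sample -> cluster id (1-based)
    tests: list[SimprofTest]
    linkage_matrix: np.ndarray
    newick: str
    alpha: float

    @property
    def n_clusters(self) -> int:
        return int(self.labels.nunique())


def _sorted_profile(sample_matrix: np.ndarray) -> np.ndarray:
    d = _bray_curtis_square(sample_matrix)
    iu = np.triu_indices(sample_matrix.shape[0], k=1)
    return np.sort(d[iu])


def _permute_within_features(
    feature_matrix: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Independently permute each feature's values across samples."""
    idx = rng.random(feature_matrix.shape).argsort(axis=1)
    return np.take_along_axis(feature_matrix, idx, axis=1)


def _simprof_pvalue(
    feature_matrix: np.ndarray,
    n_perm_expected: int,
    n_perm_test: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Similarity-profile statistic and permutation p-value at one node.

    The statistic pi sums the absolute departures of the ordered
    observed dissimilarities from the mean ordered profile under
    within-feature permutation (which destroys any multivariate group
    structure while keeping each feature's marginal distribution).
    """
    observed = _sorted_profile(feature_matrix.T)
    expected = np.zeros_like(observed)
    for _ in range(n_perm_expected):
        perm = _permute_within_features(feature_matrix, rng)
        expected += _sorted_profile(perm.T)
    expected /= n_perm_expected
    pi_obs = float(np.abs(observed - expected).sum())
    hits = 0
    for _ in range(n_perm_test):
        perm = _permute_within_features(feature_matrix, rng)
        pi_perm = float(np.abs(_sorted_profile(perm.T) - expected).sum())
        if pi_perm >= pi_obs - 1e-12:
            hits += 1
    return pi_obs, (1 + hits) / (1 + n_perm_test)


def _tree_to_newick(node, ids: list[str]) -> str:
    def rec(nd, parent_dist: float) -> str:
        length = max(parent_dist - nd.dist, 0.0)
        if nd.is_leaf():
            return f"{ids[nd.id]}:{length:.6g}"
        left = rec(nd.left, nd.dist)
        right = rec(nd.right, nd.dist)
        return f"({left},{right}):{length:.6g}"

    if node.is_leaf():
        return f"{ids[node.id]}:0;"
    left = rec(node.left, node.dist)
    right = rec(node.right, node.dist)
    return f"({left},{right});"


def simprof_cluster(
    matrix: pd.DataFrame,
    alpha: float = 0.05,
    n_perm_expected: int = 1000,
    n_perm_test: int = 999,
    seed: int | None = None,
) -> SimprofResult:
    """Average-linkage clustering pruned by similarity-profile tests.

    Samples (columns) are clustered on Bray-Curtis dissimilarities;
    starting from the root, each node's samples are tested for internal
    structure and the dendrogram is descended only where the test is
    significant at ``alpha``. The leaves of the pruned recursion are
    the reported clusters, a partition of the samples. Groups of fewer
    than three samples are untestable and returned as-is; a two-sample
    input yields a single cluster with a notice.
    """
    ids = list(matrix.columns)
    n = len(ids)
    if n < 2:
        raise ParameterError("SIMPROF needs at least two samples")
    values = matrix.to_numpy(dtype=float)
    dist = DistanceMatrix(_bray_curtis_square(values.T), ids)
    if n == 2:
        warnings.warn("two samples: similarity profile is untestable")
        labels = pd.Series([1, 1], index=ids, name="cluster")
        lm = linkage(dist.condensed(), method="average")
        return SimprofResult(
            labels=labels,
            tests=[],
            linkage_matrix=lm,
            newick=_tree_to_newick(to_tree(lm), ids),
            alpha=alpha,
        )

    lm = linkage(dist.condensed(), method="average")
    root = to_tree(lm)
    rng = np.random.default_rng(seed)
    tests: list[SimprofTest] = []
    clusters: list[list[int]] = []

    def descend(node) -> None:
        members = node.pre_order(lambda leaf: leaf.id)
        if len(members) < 3:
            clusters.append(members)
            return
        sub = values[:, members]
        pi, p = _simprof_pvalue(sub, n_perm_expected, n_perm_test, rng)
        significant = p <= alpha
        tests.append(
            SimprofTest(
                samples=[ids[i] for i in members],
                pi=pi,
                p_value=p,
                significant=significant,
            )
        )
        if significant:
            descend(node.left)
            descend(node.right)
        else:
            clusters.append(members)

    descend(root)
    label_arr = np.empty(n, dtype=int)
    for cluster_id, members in enumerate(sorted(clusters, key=min), start=1):
        label_arr[members] = cluster_id
    labels = pd.Series(label_arr, index=ids, name="cluster")
    return SimprofResult(
        labels=labels,
        tests=tests,
        linkage_matrix=lm,
        newick=_tree_to_newick(root, ids),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PcaResult:
    """Scores, loadings and percent variance from column-centered PCA."""

    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components
    percent_variance: np.ndarray
    column_means: pd.Series

    def to_dict(self) -> dict:
        return {
            "percent_variance": self.percent_variance.tolist(),
            "scores": {s: row.tolist() for s, row in self.scores.iterrows()},
        }


def pca(matrix: pd.DataFrame, n_components: int | None = None) -> PcaResult:
    """Principal component analysis with samples as observations.

    The (samples x features) matrix is column-centered but not scaled;
    the decomposition is by singular values, and percent variance per
    component is its variance over the total variance. Percent values
    over all components sum to 100.
    """
    x = matrix.to_numpy(dtype=float).T  # samples x features
    n, p = x.shape
    if n < 2:
        raise ParameterError("PCA needs at least two samples")
    max_components = min(n, p)
    if n_components is None:
        n_components = max_components
    if not (1 <= n_components <= max_components):
        raise ParameterError(
            f"n_components must be in [1, {max_components}], got {n_components}"
        )
    means = x.mean(axis=0)
    centered = x - means
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    variances = s**2 / (n - 1)
    total = variances.sum()
    percent = (
        100.0 * variances / total if total > 0 else np.zeros_like(variances)
    )
    if total == 0:
        percent = np.zeros(max_components)
    comp_ids = [f"PC{i + 1}" for i in range(n_components)]
    scores = pd.DataFrame(
        (u * s)[:, :n_components], index=matrix.columns, columns=comp_ids
    )
    loadings = pd.DataFrame(
        vt.T[:, :n_components], index=matrix.index, columns=comp_ids
    )
    return PcaResult(
        scores=scores,
        loadings=loadings,
        percent_variance=percent[:n_components],
        column_means=pd.Series(means, index=matrix.index),
    )


# ---------------------------------------------------------------------------
# per-feature ANOVA


def per_feature_anova(matrix: pd.DataFrame, groups) -> pd.DataFrame:
    """One-way fixed-effects ANOVA for every feature, BH-adjusted.

    Returns a DataFrame with per-feature F, raw p, Benjamini-Hochberg q
    and a ``degenerate`` flag. A feature with zero within-group
    variance and equal group means gets F = 0, p = 1; zero within-group
    variance with unequal means is a perfect separation, reported with
    the minimum representable p and flagged.
    """
    codes, uniques = _group_codes(groups)
    if len(uniques) < 2:
        raise DataError("ANOVA needs at least two groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        raise DataError("every group needs at least two samples")
    x = matrix.to_numpy(dtype=float)  # features x samples
    if x.shape[1] != len(codes):
        raise DimensionError("group labels do not match sample count")
    a = len(uniques)
    n = x.shape[1]
    grand = x.mean(axis=1, keepdims=True)
    ss_between = np.zeros(x.shape[0])
    ss_within = np.zeros(x.shape[0])
    for g in range(a):
        idx = codes == g
        sub = x[:, idx]
        gm = sub.mean(axis=1, keepdims=True)
        ss_between += idx.sum() * (gm[:, 0] - grand[:, 0]) ** 2
        ss_within += ((sub - gm) ** 2).sum(axis=1)
    df1, df2 = a - 1, n - a
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = (ss_between / df1) / (ss_within / df2)
    degenerate = ss_within <= 1e-300
    equal_means = ss_between <= 1e-300
    f_stat = np.where(degenerate & equal_means, 0.0, f_stat)
    f_stat = np.where(degenerate & ~equal_means, np.inf, f_stat)
    p = f_dist.sf(f_stat, df1, df2)
    p = np.where(degenerate & equal_means, 1.0, p)
    p = np.where(degenerate & ~equal_means, np.nextafter(0.0, 1.0), p)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {
            "F": f_stat,
            "p": p,
            "q": q,
            "degenerate": degenerate & ~equal_means,
        },
        index=matrix.index,
    )
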
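"""Differential expression without replicates, plus sample-similarity
clustering and PCA.

The no-replicate path treats each sample as a digital expression profile:
the two columns are quantile-normalized so both carry the same count
distribution, normalized counts are rounded back to integers, and each
feature is tested with a two-sided Fisher's exact test on the 2x2 table

    [[a, N_test - a], [b, N_control - b]]

where a, b are the feature's counts and N the column totals (the standard
feature-vs-rest formulation for digital gene expression). Benjamini-
Hochberg adjusted p-values are always computed, but the default call uses
the raw p-value against alpha with a symmetric signed fold-change
threshold; use_adjusted_p switches the call to the adjusted values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .core_io import CountTable
from .countstats import CorrectionFactor, corrected_fold_change


@dataclass
class DEParams:
    fc_threshold: float = 1.5
    p_threshold: float = 0.05
    use_adjusted_p: bool = False
    correction: CorrectionFactor | None = None

    def __post_init__(self) -> None:
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must be in (0, 1]")


@dataclass
class DERecord:
    feature_id: str
    rna_class: str
    count_test: float
    count_control: float
    norm_test: float
    norm_control: float
    signed_fc: float
    p_value: float
    adj_p: float
    call: str  # up / down / unchanged


@dataclass
class DESummary:
    n_up: int
    n_down: int
    n_unchanged: int

    @property
    def n_total(self) -> int:
        return self.n_up + self.n_down + self.n_unchanged

    @property
    def pct_unchanged(self) -> float:
        return 100.0 * self.n_unchanged / self.n_total if self.n_total else float("nan")


def quantile_normalize(table: CountTable) -> CountTable:
    """Rank-mean quantile normalization across samples.

    Each column is sorted, values at each rank are averaged across columns,
    and every entry is replaced by the mean for its rank; ties within a
    column receive the mean of the rank means they span. Afterwards every
    column carries the same multiset of values (up to tie averaging).
    """
    if len(table.samples) < 2:
        warnings.warn("quantile normalization of a single sample is the identity")
        return CountTable(list(table.features), list(table.samples), table.counts.copy())
    x = table.counts
    order = np.sort(x, axis=0)
    rank_means = order.mean(axis=1)
    normed = np.empty_like(x, dtype=float)
    for j in range(x.shape[1]):
        order = np.argsort(x[:, j], kind="stable")
        col_sorted = x[order, j]
        _, inv = np.unique(col_sorted, return_inverse=True)
        tie_means = np.bincount(inv, weights=rank_means) / np.bincount(inv)
        normed[order, j] = tie_means[inv]
    return CountTable(list(table.features), list(table.samples), normed)


def fisher_test(a: int, b: int, n_test: int, n_control: int) -> float:
    """Two-sided Fisher's exact p for counts a of n_test vs b of n_control.

    The p-value is the sum of hypergeometric probabilities, over all 2x2
    tables with the observed margins, of tables no more probable than the
    observed one (minimum-likelihood two-sided definition).
    """
    if n_test <= 0 or n_control <= 0:
        raise ValueError("column totals must be positive")
    if not (0 <= a <= n_test and 0 <= b <= n_control):
        raise ValueError("counts must lie within their column totals")
    return float(
        stats.fisher_exact([[a, n_test - a], [b, n_control - b]], alternative="two-sided")[1]
    )


def adjust_pvalues(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x) + 0.5)


def differential_expression(
    table: CountTable,
    test_sample: str,
    control_sample: str,
    params: DEParams | None = None,
) -> tuple[list[DERecord], DESummary]:
    """No-replicate differential expression between two samples.

    Pipeline: quantile-normalize the two columns, round the normalized
    counts to the nearest integer (half away from zero), Fisher-test each
    feature against the column totals, BH-adjust, compute the signed
    fold-change from normalized counts (with the additive correction
    factor, if any), and call up/down/unchanged by |FC| >= fc_threshold
    and p <= p_threshold.
    """
    params = params or DEParams()
    raw_test = table.column(test_sample)
    raw_control = table.column(control_sample)
    pair = CountTable(
        features=list(table.features),
        samples=[test_sample, control_sample],
        counts=np.column_stack([raw_test, raw_control]),
    )
    normed = quantile_normalize(pair)
    a = _round_half_away(normed.counts[:, 0]).astype(np.int64)
    b = _round_half_away(normed.counts[:, 1]).astype(np.int64)
    n_test = int(a.sum())
    n_control = int(b.sum())
    p = np.array([fisher_test(int(ai), int(bi), n_test, n_control) for ai, bi in zip(a, b)])
    adj = adjust_pvalues(p)
    k = params.correction.k if params.correction is not None else 0.0

    records: list[DERecord] = []
    n_up = n_down = 0
    p_used = adj if params.use_adjusted_p else p
    for i, (fid, cls) in enumerate(table.features):
        if b[i] + k == 0 and a[i] + k == 0:
            fc = 1.0  # both absent: no change by convention
        elif b[i] + k == 0:
            fc = float("inf")
        else:
            fc = corrected_fold_change(float(a[i]), float(b[i]), k)
        significant = abs(fc) >= params.fc_threshold and p_used[i] <= params.p_threshold
        if significant and fc >= params.fc_threshold:
            call = "up"
            n_up += 1
        elif significant and fc <= -params.fc_threshold:
            call = "down"
            n_down += 1
        else:
            call = "unchanged"
        records.append(
            DERecord(
                feature_id=fid,
                rna_class=cls,
                count_test=float(raw_test[i]),
                count_control=float(raw_control[i]),
                norm_test=float(a[i]),
                norm_control=float(b[i]),
                signed_fc=float(fc),
                p_value=float(p[i]),
                adj_p=float(adj[i]),
                call=call,
            )
        )
    summary = DESummary(n_up=n_up, n_down=n_down, n_unchanged=len(records) - n_up - n_down)
    return records, summary


def records_to_frame(records: list[DERecord]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in records])
    if not df.empty:
        df["signed_fc"] = df["signed_fc"].round(2)
    return df


def correlation_distance_matrix(table: CountTable) -> np.ndarray:
    """Pairwise 1 - Pearson correlation between sample columns. Constant
    columns have undefined correlation; they are treated as uncorrelated
    (distance 1) with everything, matching the 'no shared signal' reading."""
    x = table.counts
    n = x.shape[1]
    sd = x.std(axis=0)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if sd[i] == 0 or sd[j] == 0:
                r = 0.0
            else:
                r = float(np.corrcoef(x[:, i], x[:, j])[0, 1])
            d[i, j] = d[j, i] = 1.0 - r
    return d


def hierarchical_cluster(table: CountTable, method: str = "average"):
    """Average-linkage clustering of samples under correlation distance.

    Returns (linkage matrix, leaf order as sample names, distance matrix).
    Merge order is deterministic; SciPy breaks distance ties on the smaller
    cluster index.
    """
    if len(table.samples) < 2:
        raise ValueError("clustering needs at least 2 samples")
    d = correlation_distance_matrix(table)
    condensed = squareform(np.maximum(d, 0.0), checks=False)
    z = hierarchy.linkage(condensed, method=method)
    leaves = hierarchy.leaves_list(z)
    return z, [table.samples[i] for i in leaves], d


def dendrogram_newick(z: np.ndarray, labels: list[str]) -> str:
    """Render a SciPy linkage matrix as a Newick string with branch heights."""
    tree = hierarchy.to_tree(z)

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0) if parent_height is not None else 0.0
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    def render_root(node) -> str:
        if node.is_leaf():
            return f"{labels[node.id]};"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right});"

    return render_root(tree)


def pca(table: CountTable, n_components: int | None = None):
    """PCA of samples over feature space (features centered).

    Returns (coordinates: samples x components, variance fractions).
    Variance fractions sum to <= 1 over the reported components; a
    constant matrix has zero total variance and all-zero fractions.
    """
    if len(table.samples) < 2:
        raise ValueError("PCA needs at least 2 samples")
    x = table.counts.T  # samples x features
    x = x - x.mean(axis=0, keepdims=True)
    n_samples = x.shape[0]
    max_comp = min(n_samples - 1, x.shape[1])
    if n_components is None:
        n_components = max_comp
    n_components = min(n_components, max_comp)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    total_var = float((x**2).sum())
    coords = u[:, :n_components] * s[:n_components]
    if total_var == 0:
        fractions = np.zeros(n_components)
        coords = np.zeros_like(coords)
    else:
        fractions = (s[:n_components] ** 2) / total_var
    return coords, fractions
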
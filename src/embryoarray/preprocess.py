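"""RMA-style preprocessing: quantile normalization, median-polish probe
summarization, replicate-correlation QC and bootstrapped sample clustering.

The summarization path is the two standard RMA steps — cross-array quantile
normalization of PM intensities followed by per-probe-set median polish of
log2(PM) — without the normal+exponential background-correction step, which
gene-level analyses here do not require (see docs/methods.md).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .containers import ExpressionMatrix, ProbeIntensityTable


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column to the common distribution of cross-column rank means.

    Each column is sorted, the mean across columns is taken at every rank,
    and the means are mapped back through each column's own ranks (ties get
    the average of their rank means).  Row and column order are preserved.
    """
    if matrix.shape[1] < 1:
        raise ValueError("need at least one column")
    values = matrix.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("missing values are not allowed")
    order = np.argsort(values, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    rank_means = sorted_vals.mean(axis=1)
    out = np.empty_like(values)
    n = values.shape[0]
    for j in range(values.shape[1]):
        ranks = np.empty(n, dtype=int)
        ranks[order[:, j]] = np.arange(n)
        col = rank_means[ranks]
        # average rank means over tied input values so ties stay tied
        uniq, inv = np.unique(values[:, j], return_inverse=True)
        if len(uniq) < n:
            sums = np.bincount(inv, weights=col)
            counts = np.bincount(inv)
            col = (sums / counts)[inv]
        out[:, j] = col
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# median polish
# ---------------------------------------------------------------------------

def median_polish(
    matrix: np.ndarray, tol: float = 1e-10, max_iter: int = 100
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Tukey median polish of a probes x samples matrix.

    Alternating row/column median sweeps fit the additive decomposition
    ``x_ij = overall + row_i + col_j + resid_ij``; iteration stops when the
    largest absolute change of any effect in a sweep is below ``tol``.
    Returns (overall, row_effects, col_effects, residuals).
    """
    resid = np.asarray(matrix, dtype=float).copy()
    n_rows, n_cols = resid.shape
    overall = 0.0
    row_eff = np.zeros(n_rows)
    col_eff = np.zeros(n_cols)
    for _ in range(max_iter):
        row_med = np.median(resid, axis=1)
        resid -= row_med[:, None]
        row_eff += row_med
        med_col_eff = np.median(col_eff)
        col_eff -= med_col_eff
        overall += med_col_eff

        col_med = np.median(resid, axis=0)
        resid -= col_med[None, :]
        col_eff += col_med
        med_row_eff = np.median(row_eff)
        row_eff -= med_row_eff
        overall += med_row_eff

        delta = max(np.abs(row_med).max(), np.abs(col_med).max())
        if delta < tol:
            break
    return overall, row_eff, col_eff, resid


def median_polish_summarize(
    pm: pd.DataFrame, tol: float = 1e-10, max_iter: int = 100
) -> pd.Series:
    """Summarize one probe set: per-sample log2 expression ``overall + col_j``.

    ``pm`` is the probes x samples PM matrix on the linear scale.
    """
    if pm.shape[0] < 1 or pm.shape[1] < 1:
        raise ValueError("need at least one probe and one sample")
    values = pm.to_numpy(dtype=float)
    if (values <= 0).any():
        raise ValueError("PM intensities must be positive before log2")
    overall, _, col_eff, _ = median_polish(np.log2(values), tol=tol, max_iter=max_iter)
    return pd.Series(overall + col_eff, index=pm.columns)


def rma_summarize(
    probes: ProbeIntensityTable, tol: float = 1e-10, max_iter: int = 100
) -> ExpressionMatrix:
    """Quantile-normalize PM across arrays, then median-polish per probe set."""
    pm_wide = probes.data.pivot(
        index=["probe_set_id", "probe_index"], columns="sample_id", values="PM"
    ).loc[:, probes.sample_ids]
    normalized = quantile_normalize(pm_wide)
    rows = {}
    for probe_set_id, block in normalized.groupby(level="probe_set_id", sort=True):
        rows[probe_set_id] = median_polish_summarize(
            block.droplevel("probe_set_id"), tol=tol, max_iter=max_iter
        )
    values = pd.DataFrame(rows).T.loc[:, probes.sample_ids]
    return ExpressionMatrix(values, probes.samples)


# ---------------------------------------------------------------------------
# replicate-correlation QC
# ---------------------------------------------------------------------------

def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r with (n-1) denominators; NaN-free contract upstream."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd @ xd) * (yd @ yd))
    if denom == 0:
        raise FloatingPointError("zero variance")
    return float((xd @ yd) / denom)


def replicate_correlation(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Pearson r between biological replicates of each (genotype, stage) cell.

    With two replicates one r per cell is reported; with more, every pair.
    A zero-variance replicate yields an ``undefined`` flag instead of NaN
    propagation.
    """
    rows = []
    for genotype, stage in matrix.cells():
        ids = matrix.samples_in_cell(genotype, stage)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                try:
                    r = pearson(
                        matrix.values[ids[i]].to_numpy(),
                        matrix.values[ids[j]].to_numpy(),
                    )
                    undefined = False
                except FloatingPointError:
                    r, undefined = np.nan, True
                rows.append(
                    {
                        "genotype": genotype,
                        "stage": stage,
                        "sample_a": ids[i],
                        "sample_b": ids[j],
                        "r": r,
                        "undefined": undefined,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bootstrapped hierarchical clustering of samples
# ---------------------------------------------------------------------------

def _correlation_distance(values: np.ndarray) -> np.ndarray:
    """1 - Pearson distance matrix between columns (samples) over genes."""
    corr = np.corrcoef(values.T)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, None)


def _cluster_leafsets(link: np.ndarray, n_leaves: int) -> list[frozenset]:
    """Leaf-index sets of every internal node of a scipy linkage tree."""
    members: dict[int, frozenset] = {i: frozenset([i]) for i in range(n_leaves)}
    out = []
    for k, (a, b, _, _) in enumerate(link):
        merged = members[int(a)] | members[int(b)]
        members[n_leaves + k] = merged
        out.append(merged)
    return out


class Dendrogram:
    """Average-linkage sample tree with bootstrap support per internal node."""

    def __init__(self, link: np.ndarray, labels: list[str], supports: np.ndarray):
        self.linkage = link
        self.labels = list(labels)
        self.supports = np.asarray(supports, dtype=float)
        if not ((self.supports >= 0) & (self.supports <= 100)).all():
            raise ValueError("supports must be percentages in [0, 100]")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def leafsets(self) -> list[frozenset]:
        return _cluster_leafsets(self.linkage, self.n_leaves)

    def support_for(self, leaf_labels: set[str]) -> float | None:
        """Bootstrap support of the cluster with exactly these leaves."""
        want = frozenset(self.labels.index(x) for x in leaf_labels)
        for ls, sup in zip(self.leafsets(), self.supports):
            if ls == want:
                return float(sup)
        return None

    def to_newick(self) -> str:
        """Newick string with supports as internal-node labels and branch
        lengths from merge heights."""
        n = self.n_leaves

        def height(i: int) -> float:
            return 0.0 if i < n else float(self.linkage[i - n, 2])

        def node(i: int, parent_height: float) -> str:
            length = parent_height - height(i)
            if i < n:
                return f"{self.labels[i]}:{length:.6g}"
            k = i - n
            a, b, h, _ = self.linkage[k]
            inner = f"{node(int(a), h)},{node(int(b), h)}"
            return f"({inner}){self.supports[k]:.1f}:{length:.6g}"

        root = 2 * n - 2
        k = root - n
        a, b, h, _ = self.linkage[k]
        return f"({node(int(a), h)},{node(int(b), h)}){self.supports[k]:.1f};"


def bootstrap_hclust(
    matrix: ExpressionMatrix,
    n_boot: int = 100,
    seed: int = 0,
    resample_indices: np.ndarray | None = None,
) -> Dendrogram:
    """Average-linkage clustering of samples on 1 - Pearson distance over
    genes, with gene-resampling bootstrap proportions per internal node.

    ``resample_indices`` (n_boot x n_genes) overrides the seeded resampler;
    the test oracle shares indices through it.
    """
    if matrix.values.shape[1] < 3:
        raise ValueError("need at least 3 samples to cluster")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    values = matrix.values.to_numpy()
    n_genes = values.shape[0]
    link = linkage(squareform(_correlation_distance(values), checks=False),
                  method="average")
    original = _cluster_leafsets(link, values.shape[1])

    if resample_indices is None:
        rng = np.random.default_rng(seed)
        resample_indices = rng.integers(0, n_genes, size=(n_boot, n_genes))
    else:
        resample_indices = np.asarray(resample_indices)
        n_boot = resample_indices.shape[0]

    hits = np.zeros(len(original))
    for b in range(n_boot):
        sub = values[resample_indices[b]]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant resample columns
            d = _correlation_distance(sub)
        d = np.nan_to_num(d, nan=1.0)
        boot_link = linkage(squareform(d, checks=False), method="average")
        boot_sets = set(_cluster_leafsets(boot_link, values.shape[1]))
        for i, ls in enumerate(original):
            if ls in boot_sets:
                hits[i] += 1
    supports = 100.0 * hits / n_boot
    return Dendrogram(link, list(matrix.values.columns), supports)
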
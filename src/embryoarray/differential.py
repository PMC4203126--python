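"""Per-stage genotype contrasts: fold change, SAM-style permutation testing
and the q < 0.05 / |FC| >= 2 selection gate.

The statistic is the two-class unpaired SAM score d = (mean_B - mean_A) /
(s + s0) with the SAM pooled standard error; with two replicates per group
the permutation null enumerates all six balanced relabelings, and the FDR
at a |d| threshold is the median null exceedance count over the observed
count, monotonized into per-gene q-values.  A Benjamini-Hochberg adjustment
of pooled permutation p-values is reported alongside as a secondary
estimator.  An F-like multiclass score is available for multi-group
screens.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix


@dataclass(frozen=True)
class Contrast:
    """Two-group comparison B vs A within one stage (B = mutant genotype)."""

    stage: str
    genotype_a: str = "WT"
    genotype_b: str = "vtc2"

    def columns(self, matrix: ExpressionMatrix) -> tuple[list[str], list[str]]:
        a = matrix.samples_in_cell(self.genotype_a, self.stage)
        b = matrix.samples_in_cell(self.genotype_b, self.stage)
        if not a or not b:
            raise ValueError(f"contrast {self} has an empty group")
        return a, b


# ---------------------------------------------------------------------------
# fold change
# ---------------------------------------------------------------------------

def fold_change(matrix: ExpressionMatrix, contrast: Contrast) -> pd.DataFrame:
    """Signed linear fold change per gene.

    delta = mean log2(B) - mean log2(A); linear magnitude 2^|delta| carries
    the sign of delta (negative = down in B), the signed convention of
    published differential tables.  FC is +-1 at delta = 0.
    """
    cols_a, cols_b = contrast.columns(matrix)
    delta = matrix.values[cols_b].mean(axis=1) - matrix.values[cols_a].mean(axis=1)
    magnitude = 2.0 ** delta.abs()
    signed = np.where(delta < 0, -magnitude, magnitude)
    return pd.DataFrame({"log2FC": delta, "FC_signed": signed}, index=matrix.values.index)


# ---------------------------------------------------------------------------
# SAM statistic
# ---------------------------------------------------------------------------

def _sam_d(values: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray, s0: float):
    a = values[:, idx_a]
    b = values[:, idx_b]
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 samples per group")
    diff = b.mean(axis=1) - a.mean(axis=1)
    ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (b - b.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s = np.sqrt((1.0 / na + 1.0 / nb) / (na + nb - 2) * ss)
    denom = s + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(denom > 0, diff / denom, np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
    return d, s


def sam_statistic(
    matrix: ExpressionMatrix, contrast: Contrast, s0: float | None = None
) -> pd.DataFrame:
    """Per-gene SAM d statistic; s0 defaults to the median gene-wise s.

    Genes with zero within-group variance and s0 = 0 get an infinite d,
    flagged in the ``infinite`` column; downstream permutation nulls
    exclude them.
    """
    cols_a, cols_b = contrast.columns(matrix)
    values = matrix.values.to_numpy()
    all_cols = list(matrix.values.columns)
    idx_a = np.array([all_cols.index(c) for c in cols_a])
    idx_b = np.array([all_cols.index(c) for c in cols_b])
    _, s = _sam_d(values, idx_a, idx_b, 0.0)
    if s0 is None:
        s0 = float(np.median(s))
    d, s = _sam_d(values, idx_a, idx_b, s0)
    return pd.DataFrame(
        {"d": d, "s": s, "s0": s0, "infinite": ~np.isfinite(d)},
        index=matrix.values.index,
    )


def multiclass_sam_statistic(
    matrix: ExpressionMatrix, stage_groups: dict[str, list[str]], s0: float | None = None
) -> pd.Series:
    """F-like multiclass score: sqrt(between-group mean square) over (s + s0).

    ``stage_groups``: group label -> sample columns.  A screening statistic
    for designs with more than two groups; the two-class d is the primary
    path.
    """
    groups = [matrix.values[cols].to_numpy() for cols in stage_groups.values()]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    ns = np.array([g.shape[1] for g in groups])
    grand = np.hstack(groups).mean(axis=1)
    between = sum(
        n * (g.mean(axis=1) - grand) ** 2 for n, g in zip(ns, groups)
    ) / (len(groups) - 1)
    within_ss = sum(((g - g.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) for g in groups)
    s = np.sqrt(within_ss / (ns.sum() - len(groups)))
    if s0 is None:
        s0 = float(np.median(s))
    return pd.Series(np.sqrt(between) / (s + s0), index=matrix.values.index)


# ---------------------------------------------------------------------------
# permutation FDR
# ---------------------------------------------------------------------------

def balanced_relabelings(cols_a: list[str], cols_b: list[str]) -> list[tuple[list[str], list[str]]]:
    """All ways to split the pooled samples into groups of the original sizes."""
    pooled = list(cols_a) + list(cols_b)
    na = len(cols_a)
    out = []
    for pick in combinations(range(len(pooled)), na):
        a = [pooled[i] for i in pick]
        b = [pooled[i] for i in range(len(pooled)) if i not in pick]
        out.append((a, b))
    return out


def permutation_fdr(
    matrix: ExpressionMatrix,
    contrast: Contrast,
    s0: float | None = None,
    n_perm: int | str = "all",
    seed: int = 0,
) -> pd.DataFrame:
    """SAM-style q-values from the balanced-relabeling permutation null.

    For every observed |d| threshold, FDR = median over relabelings of the
    null count of |d*| >= threshold, divided by the observed count; the
    per-gene q is the minimum FDR over all thresholds at or below the
    gene's own |d| (capped at 1), which is monotone non-decreasing down the
    |d| ranking.  ``q_BH`` additionally reports a Benjamini-Hochberg
    adjustment of pooled permutation p-values.
    """
    cols_a, cols_b = contrast.columns(matrix)
    stat = sam_statistic(matrix, contrast, s0=s0)
    s0_used = float(stat["s0"].iloc[0])
    d_obs = stat["d"].to_numpy()
    abs_obs = np.abs(d_obs)

    relabelings = balanced_relabelings(cols_a, cols_b)
    if n_perm != "all":
        rng = np.random.default_rng(seed)
        take = min(int(n_perm), len(relabelings))
        keep = rng.choice(len(relabelings), size=take, replace=False)
        relabelings = [relabelings[i] for i in keep]
    if len(relabelings) < 2:
        raise ValueError("need at least 2 distinct relabelings")

    values = matrix.values.to_numpy()
    all_cols = list(matrix.values.columns)
    null_stats = []
    for a, b in relabelings:
        idx_a = np.array([all_cols.index(c) for c in a])
        idx_b = np.array([all_cols.index(c) for c in b])
        d_null, _ = _sam_d(values, idx_a, idx_b, s0_used)
        null_stats.append(np.abs(d_null[np.isfinite(d_null)]))

    order = np.argsort(-abs_obs, kind="stable")
    thresholds = abs_obs[order]
    obs_counts = np.array([(abs_obs >= t).sum() for t in thresholds])
    null_counts = np.array(
        [[(dn >= t).sum() for t in thresholds] for dn in null_stats]
    )  # perms x thresholds
    med_null = np.median(null_counts, axis=0)
    fdr = np.minimum(med_null / obs_counts, 1.0)
    # q_i = min FDR over thresholds at or below the gene's |d| (suffix min)
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted

    pooled_null = np.concatenate(null_stats) if null_stats else np.array([])
    sorted_null = np.sort(pooled_null)
    exceed = len(sorted_null) - np.searchsorted(sorted_null, abs_obs, side="left")
    p_perm = (1.0 + exceed) / (1.0 + len(sorted_null))
    q_bh = bh_adjust(p_perm)

    out = stat.copy()
    out["q_SAM"] = q
    out["p_perm"] = p_perm
    out["q_BH"] = q_bh
    return out


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# selection gate
# ---------------------------------------------------------------------------

def diff_test(
    matrix: ExpressionMatrix,
    contrast: Contrast,
    s0: float | None = None,
    q_threshold: float = 0.05,
    fc_threshold: float = 2.0,
    q_column: str = "q_SAM",
) -> pd.DataFrame:
    """Full per-contrast result: d, fold change, q-values, selection flag.

    Selected iff q < ``q_threshold`` and linear |FC| >= ``fc_threshold``
    (the fold-change bound is inclusive: exactly 2-fold passes).
    """
    fc = fold_change(matrix, contrast)
    stat = permutation_fdr(matrix, contrast, s0=s0)
    result = pd.concat([fc, stat], axis=1)
    result["selected"] = selection_mask(
        result[q_column], result["FC_signed"], q_threshold, fc_threshold
    )
    return result


def selection_mask(
    q_values, fc_signed, q_threshold: float = 0.05, fc_threshold: float = 2.0
) -> np.ndarray:
    """q < threshold AND linear |FC| >= threshold (inclusive at the bound)."""
    q = np.asarray(q_values, dtype=float)
    fc = np.asarray(fc_signed, dtype=float)
    return (q < q_threshold) & (np.abs(fc) >= fc_threshold)


def select_deg(result: pd.DataFrame, fc_threshold: float = 2.0) -> dict[str, list[str]]:
    """Split selected genes into up/down lists with counts."""
    sel = result[result["selected"]]
    up = sel.index[sel["FC_signed"] >= fc_threshold].tolist()
    down = sel.index[sel["FC_signed"] <= -fc_threshold].tolist()
    return {"up": up, "down": down, "n_up": len(up), "n_down": len(down)}
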
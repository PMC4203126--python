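"""Dominant-pattern discovery: low-expression filter, FANNY fuzzy K-means,
correlation-based prototype merging and correlation-gated gene assignment.

The procedure works on the replicate-averaged expression matrix: genes
whose linear-scale value is <= 30 in every (genotype, stage) cell are
removed, each remaining gene's profile is z-standardized over the cells,
and profiles are clustered with the Kaufman-Rousseeuw fuzzy algorithm
(FANNY) on 1 - Pearson dissimilarity, K = 15 by default.  Cluster cores
(membership >= m = 0.44 and argmax) define prototypes; prototypes whose
Pearson correlation reaches the merge threshold are grouped into dominant
patterns; finally every filtered gene is assigned to its best-correlated
pattern iff that correlation is >= 0.85.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import DominantPatternSet, ExpressionMatrix, FuzzyPartition


# ---------------------------------------------------------------------------
# filtering and standardization
# ---------------------------------------------------------------------------

def filter_low_expression(
    matrix: ExpressionMatrix, threshold: float = 30.0
) -> pd.DataFrame:
    """Replicate-averaged log2 matrix minus genes at or below ``threshold``.

    The filter is on the linear scale: a gene is removed iff its mean
    linear value (2**log2, averaged over the replicates of each cell) is
    <= threshold in ALL cells (the bound is inclusive; a relative 1e-12
    guard absorbs log/exp round-trip error at the boundary).  Returns the
    replicate-averaged log2 matrix (genes x ``genotype:stage`` cells) of
    the retained genes; an empty result is a valid degenerate output.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    means = matrix.cell_means()
    linear_cols = {}
    for genotype, stage in matrix.cells():
        ids = matrix.samples_in_cell(genotype, stage)
        linear_cols[f"{genotype}:{stage}"] = (
            2.0 ** matrix.values[ids]
        ).mean(axis=1)
    linear = pd.DataFrame(linear_cols, index=matrix.values.index)
    keep = (linear > threshold * (1 + 1e-12)).any(axis=1)
    return means.loc[keep]


def standardize_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-standardization over cells; zero-variance rows are dropped
    with a warning (their Pearson correlation is undefined)."""
    values = profiles.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(f"dropping {int(flat.sum())} constant profiles")
    values = values[~flat]
    z = (values - values.mean(axis=1, keepdims=True)) / sd[~flat][:, None]
    return pd.DataFrame(z, index=profiles.index[~flat], columns=profiles.columns)


def pearson_dissimilarity(profiles: pd.DataFrame) -> np.ndarray:
    """d_ij = 1 - Pearson r between gene profiles."""
    corr = np.corrcoef(profiles.to_numpy(dtype=float))
    corr = np.atleast_2d(corr)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


# ---------------------------------------------------------------------------
# FANNY fuzzy clustering
# ---------------------------------------------------------------------------

def fanny_objective(u: np.ndarray, d: np.ndarray, memb_exp: float = 2.0) -> float:
    """Kaufman-Rousseeuw objective:
    sum_v (sum_ij u_iv^r u_jv^r d_ij) / (2 sum_j u_jv^r)."""
    ur = u**memb_exp
    total = 0.0
    for v in range(u.shape[1]):
        w = ur[:, v]
        denom = 2.0 * w.sum()
        if denom == 0:
            continue
        total += float(w @ d @ w) / denom
    return total


def _initial_membership(d: np.ndarray, k: int, rng) -> np.ndarray:
    """Maxmin-seeded initial memberships with a small Dirichlet perturbation.

    k seed objects are chosen by farthest-point traversal of the
    dissimilarity matrix; memberships start inversely proportional to the
    dissimilarity to each seed.  This lands the iteration in a basin near
    well-separated structure when there is one; the seeded jitter breaks
    symmetry when there is none.
    """
    n = d.shape[0]
    seeds = [int(np.argmin(d.sum(axis=1)))]
    while len(seeds) < k:
        min_d = d[:, seeds].min(axis=1)
        min_d[seeds] = -1.0
        seeds.append(int(np.argmax(min_d)))
    inv = 1.0 / (d[:, seeds] + 1e-6)
    u = inv / inv.sum(axis=1, keepdims=True)
    u = 0.95 * u + 0.05 * rng.dirichlet(np.ones(k), size=n)
    return u / u.sum(axis=1, keepdims=True)


def fanny_cluster(
    profiles: pd.DataFrame,
    k: int = 15,
    memb_exp: float = 2.0,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> FuzzyPartition:
    """Fuzzy clustering of standardized gene profiles on 1 - Pearson
    dissimilarity, minimizing the Kaufman-Rousseeuw objective.

    Memberships start from a seeded symmetric Dirichlet and are updated by
    the classic FANNY iteration (each row proportional to the inverse
    partial derivative of the objective, exponent 1/(r-1)); a halving
    damper guarantees the objective never increases.  Convergence is a
    relative objective change below ``tol``.
    """
    n = profiles.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available genes")
    d = pearson_dissimilarity(profiles)
    if k == 1:
        u = np.ones((n, 1))
        return FuzzyPartition(
            membership=pd.DataFrame(u, index=profiles.index, columns=["C1"]),
            objective=fanny_objective(u, d, memb_exp),
            n_iter=0,
        )

    rng = np.random.default_rng(seed)
    u = _initial_membership(d, k, rng)
    obj = fanny_objective(u, d, memb_exp)
    converged = False
    it = 0
    inv_exp = 1.0 / (memb_exp - 1.0)
    for it in range(1, max_iter + 1):
        ur = u**memb_exp
        p = ur.sum(axis=0)  # cluster masses
        a = d @ ur  # a[i, v] = sum_j u_jv^r d_ij
        s = np.einsum("iv,iv->v", ur, a)  # sum_ij u^r u^r d
        with np.errstate(divide="ignore", invalid="ignore"):
            e = a / p[None, :] - (s / (2.0 * p**2))[None, :]
        e = np.where(p[None, :] > 0, e, np.inf)

        new_u = np.empty_like(u)
        nonpos = e <= 1e-12
        rows_nonpos = nonpos.any(axis=1)
        with np.errstate(divide="ignore", over="ignore"):
            inv = (1.0 / np.where(e > 1e-12, e, np.inf)) ** inv_exp
        sums = inv.sum(axis=1)
        ok = ~rows_nonpos & (sums > 0) & np.isfinite(sums)
        new_u[ok] = inv[ok] / sums[ok, None]
        # a non-positive partial derivative pins the row to its best cluster
        for i in np.flatnonzero(~ok):
            best = int(np.argmin(e[i]))
            new_u[i] = 0.0
            new_u[i, best] = 1.0

        # halving damper: never let the objective rise
        candidate = new_u
        new_obj = fanny_objective(candidate, d, memb_exp)
        halvings = 0
        while new_obj > obj and halvings < 20:
            candidate = 0.5 * (candidate + u)
            new_obj = fanny_objective(candidate, d, memb_exp)
            halvings += 1
        if new_obj > obj:
            converged = True  # no descent direction left
            break
        rel_change = abs(obj - new_obj) / max(abs(obj), 1e-300)
        u, obj = candidate, new_obj
        if rel_change < tol:
            converged = True
            break
    if not converged:
        warnings.warn("FANNY did not converge within max_iter")
    columns = [f"C{v + 1}" for v in range(k)]
    return FuzzyPartition(
        membership=pd.DataFrame(u, index=profiles.index, columns=columns),
        objective=obj,
        n_iter=it,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# cores, merging, assignment
# ---------------------------------------------------------------------------

def core_genes(
    partition: FuzzyPartition, profiles: pd.DataFrame, m: float = 0.44
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Per-cluster core sets and core-mean prototypes.

    A gene is core for cluster v iff its membership u_v >= m and v is its
    argmax cluster (ties broken toward the lowest cluster index).  Clusters
    with an empty core are dropped with a warning.
    """
    u = partition.membership
    argmax = u.to_numpy().argmax(axis=1)  # numpy argmax takes the first max
    cores: dict[str, list[str]] = {}
    prototypes = {}
    for v, cluster in enumerate(u.columns):
        in_core = (u[cluster].to_numpy() >= m) & (argmax == v)
        members = list(u.index[in_core])
        if not members:
            warnings.warn(f"cluster {cluster} has an empty core; dropped")
            continue
        cores[cluster] = members
        prototypes[cluster] = profiles.loc[members].mean(axis=0)
    if not cores:
        raise ValueError(
            f"every cluster core is empty at m={m}; lower the membership threshold"
        )
    return cores, pd.DataFrame(prototypes).T


def merge_clusters(
    prototypes: pd.DataFrame,
    sizes: dict[str, int] | None = None,
    merge_r: float = 0.90,
) -> DominantPatternSet:
    """Greedy agglomeration of prototypes by Pearson correlation.

    Repeatedly merges the pair with the highest correlation while that
    correlation is >= ``merge_r`` (ties: lowest index pair).  The merged
    prototype is the size-weighted mean of its members; provenance records
    which raw clusters built each pattern.
    """
    if prototypes.shape[0] < 1:
        raise ValueError("need at least one prototype")
    labels = list(prototypes.index)
    profiles = {lab: prototypes.loc[lab].to_numpy(dtype=float) for lab in labels}
    weights = {lab: (sizes or {}).get(lab, 1) for lab in labels}
    members: dict[str, list[str]] = {lab: [lab] for lab in labels}

    def corr(x, y):
        xd = x - x.mean()
        yd = y - y.mean()
        denom = np.sqrt((xd @ xd) * (yd @ yd))
        return float(xd @ yd / denom) if denom > 0 else np.nan

    while len(profiles) > 1:
        keys = list(profiles)
        best = None
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                r = corr(profiles[keys[i]], profiles[keys[j]])
                if np.isnan(r):
                    continue
                if best is None or r > best[0] + 1e-15:
                    best = (r, keys[i], keys[j])
        if best is None or best[0] < merge_r:
            break
        _, ka, kb = best
        wa, wb = weights[ka], weights[kb]
        profiles[ka] = (wa * profiles[ka] + wb * profiles[kb]) / (wa + wb)
        weights[ka] = wa + wb
        members[ka] = members[ka] + members[kb]
        del profiles[kb], weights[kb], members[kb]

    pattern_ids = [f"DP{i + 1}" for i in range(len(profiles))]
    proto = pd.DataFrame(
        [profiles[k] for k in profiles], index=pattern_ids, columns=prototypes.columns
    )
    provenance = {pid: members[k] for pid, k in zip(pattern_ids, profiles)}
    return DominantPatternSet(prototypes=proto, provenance=provenance)


def assign_genes(
    profiles: pd.DataFrame, patterns: DominantPatternSet, r_min: float = 0.85
) -> DominantPatternSet:
    """Assign each gene to its single best-correlated prototype iff r >= r_min.

    Constant gene profiles get an ``undefined correlation`` flag and stay
    unassigned.  Returns the pattern set with ``assignments`` filled in.
    """
    proto = patterns.prototypes.to_numpy(dtype=float)
    pz = proto - proto.mean(axis=1, keepdims=True)
    pnorm = np.linalg.norm(pz, axis=1)
    values = profiles.to_numpy(dtype=float)
    gz = values - values.mean(axis=1, keepdims=True)
    gnorm = np.linalg.norm(gz, axis=1)

    rows = []
    for i, gene in enumerate(profiles.index):
        if gnorm[i] == 0 or not np.isfinite(gnorm[i]):
            rows.append({"gene": gene, "pattern": None, "r": np.nan,
                         "flag": "undefined correlation"})
            continue
        with np.errstate(invalid="ignore"):
            r = (pz @ gz[i]) / (pnorm * gnorm[i])
        best = int(np.nanargmax(r))
        if r[best] >= r_min:
            rows.append({"gene": gene, "pattern": patterns.prototypes.index[best],
                         "r": float(r[best]), "flag": ""})
        else:
            rows.append({"gene": gene, "pattern": None, "r": float(r[best]), "flag": ""})
    assignments = pd.DataFrame(rows).set_index("gene")
    return DominantPatternSet(
        prototypes=patterns.prototypes,
        assignments=assignments,
        provenance=patterns.provenance,
    )


# ---------------------------------------------------------------------------
# full procedure
# ---------------------------------------------------------------------------

def dominant_patterns(
    matrix: ExpressionMatrix,
    k: int = 15,
    m: float = 0.44,
    assign_r: float = 0.85,
    merge_r: float = 0.90,
    expression_threshold: float = 30.0,
    seed: int = 0,
) -> tuple[DominantPatternSet, FuzzyPartition, pd.DataFrame]:
    """Filter -> standardize -> FANNY -> cores -> merge -> assign.

    Returns the assigned pattern set, the raw fuzzy partition and the
    standardized profile matrix that was clustered.  With zero genes
    surviving the filter an empty pattern set is returned.
    """
    filtered = filter_low_expression(matrix, threshold=expression_threshold)
    profiles = standardize_profiles(filtered)
    if profiles.shape[0] == 0:
        empty = DominantPatternSet(
            prototypes=pd.DataFrame(columns=filtered.columns),
            assignments=pd.DataFrame(columns=["pattern", "r", "flag"]),
        )
        return empty, FuzzyPartition(
            membership=pd.DataFrame(np.zeros((0, 1)), columns=["C1"]), objective=0.0,
            n_iter=0,
        ), profiles
    k_eff = min(k, profiles.shape[0])
    partition = fanny_cluster(profiles, k=k_eff, seed=seed)
    cores, prototypes = core_genes(partition, profiles, m=m)
    sizes = {c: len(g) for c, g in cores.items()}
    merged = merge_clusters(prototypes, sizes=sizes, merge_r=merge_r)
    return assign_genes(profiles, merged, r_min=assign_r), partition, profiles


def merge_sensitivity_sweep(
    prototypes: pd.DataFrame,
    sizes: dict[str, int] | None = None,
    thresholds=np.arange(0.70, 1.0, 0.05),
) -> pd.DataFrame:
    """Pattern count as a function of the merge threshold (the threshold the
    source procedure leaves unstated)."""
    rows = [
        {"merge_r": float(t),
         "n_patterns": merge_clusters(prototypes, sizes, merge_r=float(t)).n_patterns}
        for t in thresholds
    ]
    return pd.DataFrame(rows)
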
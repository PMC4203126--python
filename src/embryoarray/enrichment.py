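"""Hypergeometric over-representation of GO terms and promoter motifs.

A gene set (a differential list or a dominant-pattern membership) is tested
against a background universe (all genes on the array): with N background
genes, K of which carry the annotation, and a set of n genes containing k
carriers, the enrichment p-value is the upper tail P(X >= k) of the
hypergeometric distribution.  A term or motif is flagged enriched at raw
p < 0.001; Benjamini-Hochberg adjusted values are reported alongside.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .differential import bh_adjust
from .motifs import scan_sequence

ENRICH_P = 0.001


def hypergeometric_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail p-value P(X >= k), X ~ Hypergeom(N, K, n).

    Evaluated through the log-space-stable survival function; k = 0 gives
    exactly 1.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K)):
        raise ValueError(
            f"inconsistent counts: k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def _enrich_table(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(
            columns=["term", "k", "K", "n", "N", "p", "p_adjusted", "enriched"]
        )
    df["p_adjusted"] = bh_adjust(df["p"].to_numpy())
    df["enriched"] = df["p"] < ENRICH_P
    return df.sort_values(["p", "term"], kind="stable").reset_index(drop=True)


def go_enrichment(
    gene_set, gmt: dict[str, dict], background
) -> pd.DataFrame:
    """One hypergeometric test per GO term with >= 1 background member.

    Genes of the set absent from the background are dropped with a warning
    count.  Returns a table (term, k, K, n, N, p, p_adjusted, enriched).
    """
    background = set(background)
    gene_set = set(gene_set)
    stray = gene_set - background
    if stray:
        warnings.warn(f"{len(stray)} set genes absent from background; dropped")
        gene_set = gene_set & background
    N = len(background)
    n = len(gene_set)
    rows = []
    for term_id, entry in gmt.items():
        carriers = set(entry["genes"]) & background
        K = len(carriers)
        if K == 0:
            continue
        k = len(carriers & gene_set)
        rows.append(
            {"term": term_id, "k": k, "K": K, "n": n, "N": N,
             "p": hypergeometric_test(k, K, n, N)}
        )
    return _enrich_table(rows)


def log10_matrix(results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """-log10(p) matrix (terms x gene sets), heatmap-ready."""
    cols = {}
    for set_name, table in results.items():
        if table.empty:
            cols[set_name] = pd.Series(dtype=float)
        else:
            cols[set_name] = table.set_index("term")["p"].map(
                lambda p: -np.log10(max(p, 1e-300))
            )
    return pd.DataFrame(cols).fillna(0.0)


def scan_promoters(promoters: dict[str, str], motif: str) -> pd.Series:
    """Exact IUPAC match counts of ``motif`` per promoter, both strands."""
    return pd.Series(
        {gene: scan_sequence(seq, motif) for gene, seq in promoters.items()},
        name=motif, dtype=int,
    )


def motif_hit_table(
    promoters: dict[str, str], motifs: dict[str, str]
) -> pd.DataFrame:
    """Genes x motifs table of match counts."""
    return pd.DataFrame({mid: scan_promoters(promoters, cons)
                         for mid, cons in motifs.items()})


def motif_enrichment(
    gene_set,
    promoters: dict[str, str],
    motifs: dict[str, str],
    background,
    hit_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Hypergeometric enrichment of motif carriers in a gene set.

    A gene is a carrier iff its promoter has >= 1 match.  Background genes
    without a promoter sequence are excluded from the universe with a
    warning; set genes likewise.
    """
    background = set(background)
    gene_set = set(gene_set)
    missing = {g for g in background if g not in promoters}
    if missing:
        warnings.warn(f"{len(missing)} genes lack promoters; excluded")
        background -= missing
        gene_set -= missing
    gene_set &= background
    if hit_table is None:
        hit_table = motif_hit_table({g: promoters[g] for g in background}, motifs)
    N = len(background)
    n = len(gene_set)
    rows = []
    for motif_id in motifs:
        carriers = set(hit_table.index[hit_table[motif_id] > 0]) & background
        K = len(carriers)
        k = len(carriers & gene_set)
        rows.append(
            {"term": motif_id, "k": k, "K": K, "n": n, "N": N,
             "p": hypergeometric_test(k, K, n, N) if K else 1.0}
        )
    return _enrich_table(rows)
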
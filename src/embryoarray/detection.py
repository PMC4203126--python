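"""Present/Marginal/Absent detection calls from PM/MM probe pairs.

The call logic follows the classic detection-call scheme for expression
arrays: per probe pair a discrimination score R = (PM - MM)/(PM + MM), then
a one-sided Wilcoxon signed-rank test of median(R) > tau.  The p-value is
exact (full enumeration of the signed-rank null via a generating-polynomial
convolution) for up to 25 informative pairs and a tie-corrected normal
approximation beyond.  Call thresholds default to the published detection
defaults tau=0.015, alpha1=0.04, alpha2=0.06.
"""

from __future__ import annotations

import warnings
from math import erfc, sqrt

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, ProbeIntensityTable

EXACT_LIMIT = 25  # exact signed-rank enumeration up to this many pairs


def discrimination_scores(pm: np.ndarray, mm: np.ndarray) -> np.ndarray:
    """R_i = (PM_i - MM_i) / (PM_i + MM_i), each in [-1, 1].

    Pairs with PM + MM = 0 carry no signal and are dropped with a warning.
    """
    pm = np.asarray(pm, dtype=float)
    mm = np.asarray(mm, dtype=float)
    total = pm + mm
    keep = total > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} probe pairs with PM+MM=0")
    return (pm[keep] - mm[keep]) / total[keep]


def signed_rank_p(diffs: np.ndarray) -> float:
    """One-sided exact P(W+ >= observed) for the Wilcoxon signed-rank test.

    Zeros are dropped (rank-0 convention); ties in |diff| get midranks.
    Exact enumeration uses the generating polynomial over doubled midranks
    (integers even under midrank ties); above EXACT_LIMIT a tie-corrected
    normal approximation with continuity correction is used.
    """
    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[diffs != 0]
    n = len(diffs)
    if n == 0:
        return 1.0
    absd = np.abs(diffs)
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(n)
    sorted_abs = absd[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1  # midrank
        i = j + 1
    w_obs = ranks[diffs > 0].sum()

    if n <= EXACT_LIMIT:
        ranks2 = np.rint(2 * ranks).astype(int)  # doubled midranks: integers
        total = ranks2.sum()
        counts = np.zeros(total + 1, dtype=float)
        counts[0] = 1.0
        top = 0
        for r in ranks2:
            counts[r : top + r + 1] += counts[: top + 1]
            top += r
        w2_obs = int(np.rint(2 * w_obs))
        # half-integer observed sums cannot be produced exactly; >= handles it
        tail = counts[w2_obs:].sum() if w2_obs <= total else 0.0
        return float(tail / counts.sum())

    mean = ranks.sum() / 2
    tie_var = (ranks**2).sum() / 4
    if tie_var == 0:
        return 1.0
    z = (w_obs - mean - 0.5) / sqrt(tie_var)
    return 0.5 * erfc(z / sqrt(2))


def detection_call(
    scores: np.ndarray,
    tau: float = 0.015,
    alpha1: float = 0.04,
    alpha2: float = 0.06,
) -> tuple[float, str]:
    """Detection p-value and P/M/A call for one probe set on one array."""
    if not 0 < alpha1 < alpha2 < 0.5:
        raise ValueError("need 0 < alpha1 < alpha2 < 0.5")
    scores = np.asarray(scores, dtype=float)
    if len(scores) < 3:
        raise ValueError("need at least 3 discrimination scores")
    p = signed_rank_p(scores - tau)
    if p < alpha1:
        call = "P"
    elif p < alpha2:
        call = "M"
    else:
        call = "A"
    return p, call


def detection_calls(
    probes: ProbeIntensityTable,
    tau: float = 0.015,
    alpha1: float = 0.04,
    alpha2: float = 0.06,
) -> pd.DataFrame:
    """All genes x samples: long DataFrame (gene, sample, p, call)."""
    rows = []
    data = probes.data
    for (gene, sample), block in data.groupby(["probe_set_id", "sample_id"], sort=True):
        scores = discrimination_scores(block["PM"].to_numpy(), block["MM"].to_numpy())
        p, call = detection_call(scores, tau=tau, alpha1=alpha1, alpha2=alpha2)
        rows.append({"gene": gene, "sample": sample, "p": p, "call": call})
    return pd.DataFrame(rows)


def consensus_present(
    calls: pd.DataFrame, samples: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-tissue consensus: detected iff called 'P' in both replicates.

    Returns the consensus table (gene x ``genotype:stage`` booleans) and
    per-tissue detected-gene counts.  Tissues without their full replicate
    set are skipped with a warning.
    """
    merged = calls.merge(
        samples.reset_index()[["sample_id", "genotype", "stage"]],
        left_on="sample", right_on="sample_id",
    )
    expected = samples.groupby(["genotype", "stage"]).size()
    consensus = {}
    for (genotype, stage), block in merged.groupby(["genotype", "stage"], sort=False):
        n_reps = block["sample"].nunique()
        if n_reps < expected.loc[(genotype, stage)]:
            warnings.warn(f"tissue {genotype}:{stage} missing replicates; skipped")
            continue
        is_p = block.assign(isp=block["call"] == "P")
        consensus[f"{genotype}:{stage}"] = is_p.groupby("gene")["isp"].all()
    table = pd.DataFrame(consensus)
    # order columns as in the sample sheet
    ordered = []
    for _, row in samples.iterrows():
        label = f"{row['genotype']}:{row['stage']}"
        if label in table.columns and label not in ordered:
            ordered.append(label)
    table = table[ordered]
    return table, table.sum(axis=0)
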
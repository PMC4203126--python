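"""Relative qPCR quantification by the 2^-ddCt method.

For a target gene, dCt = Ct_target - Ct_reference within each condition
(replicate Ct values are averaged first); ddCt = dCt_treated -
dCt_calibrator; relative expression = 2^-ddCt.  The reference gene must be
measured in every sample, and replicate scatter is summarized by the range
method (fold bounds at ddCt -+ SD), reported but not propagated further.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("sample", "condition", "gene", "Ct")


def validate_ct_table(table: pd.DataFrame, reference: str) -> None:
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    dup = table.duplicated(subset=["sample", "gene"])
    if dup.any():
        raise ValueError("duplicate (sample, gene) Ct measurements")
    for sample, block in table.groupby("sample"):
        if reference not in set(block["gene"]):
            raise ValueError(f"reference gene missing from sample {sample!r}")


def _mean_ct(table: pd.DataFrame, gene: str, condition: str) -> tuple[float, float]:
    block = table[(table["gene"] == gene) & (table["condition"] == condition)]
    if block.empty:
        raise ValueError(f"no Ct for gene {gene!r} in condition {condition!r}")
    return float(block["Ct"].mean()), float(block["Ct"].std(ddof=1)) if len(block) > 1 else 0.0


def ddct(
    table: pd.DataFrame,
    target: str,
    reference: str,
    treated: str,
    calibrator: str,
) -> dict:
    """2^-ddCt relative expression of ``target`` in ``treated`` vs ``calibrator``.

    Returns a dict with ``fold``, the underlying dCt/ddCt values and an SD
    on ddCt combined from the per-condition target replicate scatter.
    """
    validate_ct_table(table, reference)
    ct_t_treated, sd_t_treated = _mean_ct(table, target, treated)
    ct_r_treated, _ = _mean_ct(table, reference, treated)
    ct_t_cal, sd_t_cal = _mean_ct(table, target, calibrator)
    ct_r_cal, _ = _mean_ct(table, reference, calibrator)
    dct_treated = ct_t_treated - ct_r_treated
    dct_cal = ct_t_cal - ct_r_cal
    ddct_value = dct_treated - dct_cal
    sd = float(np.sqrt(sd_t_treated**2 + sd_t_cal**2))
    fold = 2.0**-ddct_value
    return {
        "gene": target,
        "fold": fold,
        "ddCt": ddct_value,
        "dCt_treated": dct_treated,
        "dCt_calibrator": dct_cal,
        "sd_ddCt": sd,
        "fold_low": 2.0 ** -(ddct_value + sd),
        "fold_high": 2.0 ** -(ddct_value - sd),
    }


def ddct_table(
    table: pd.DataFrame,
    reference: str,
    calibrator: str,
    targets=None,
    conditions=None,
) -> pd.DataFrame:
    """Fold table (gene x condition) vs the calibrator condition."""
    validate_ct_table(table, reference)
    if targets is None:
        targets = [g for g in table["gene"].unique() if g != reference]
    if conditions is None:
        conditions = [c for c in table["condition"].unique() if c != calibrator]
    rows = []
    for gene in targets:
        for condition in conditions:
            res = ddct(table, gene, reference, condition, calibrator)
            rows.append(
                {"gene": gene, "condition": condition, "fold": res["fold"],
                 "sd_ddCt": res["sd_ddCt"]}
            )
    return pd.DataFrame(rows)
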
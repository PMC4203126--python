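"""Core in-memory containers shared across pipeline stages.

The pipeline moves three kinds of tabular data around: probe-level
perfect-match / mismatch intensities, gene-level log2 expression with
sample metadata, and per-gene results tables.  The first two get thin
wrapper classes here; results tables are plain :class:`pandas.DataFrame`
objects documented at their producing function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SAMPLE_SHEET_COLUMNS = ("sample_id", "genotype", "stage", "replicate")


@dataclass
class ProbeIntensityTable:
    """Probe-level PM/MM intensities, long format.

    ``data`` has columns ``probe_set_id, probe_index, sample_id, PM, MM``;
    ``samples`` is the sample sheet indexed by ``sample_id`` with columns
    ``genotype, stage, replicate``.
    """

    data: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"probe_set_id", "probe_index", "sample_id", "PM", "MM"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"probe table missing columns: {sorted(missing)}")

    @property
    def probe_set_ids(self) -> list[str]:
        return sorted(self.data["probe_set_id"].unique())

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    def pm_matrix(self, probe_set_id: str) -> pd.DataFrame:
        """PM intensities of one probe set as a probes x samples frame."""
        sub = self.data[self.data["probe_set_id"] == probe_set_id]
        if sub.empty:
            raise KeyError(f"unknown probe set: {probe_set_id}")
        mat = sub.pivot(index="probe_index", columns="sample_id", values="PM")
        return mat.loc[:, self.sample_ids]

    def mm_matrix(self, probe_set_id: str) -> pd.DataFrame:
        sub = self.data[self.data["probe_set_id"] == probe_set_id]
        if sub.empty:
            raise KeyError(f"unknown probe set: {probe_set_id}")
        mat = sub.pivot(index="probe_index", columns="sample_id", values="MM")
        return mat.loc[:, self.sample_ids]


class ExpressionMatrix:
    """Gene-level log2 expression (genes x samples) with sample metadata.

    Parameters
    ----------
    values : DataFrame
        log2 expression, index = gene ids, columns = sample ids.
    samples : DataFrame
        Sample sheet indexed by sample id, columns genotype / stage /
        replicate.  Column order of ``values`` is aligned to it.
    """

    def __init__(self, values: pd.DataFrame, samples: pd.DataFrame):
        if not values.index.is_unique:
            raise ValueError("gene ids must be unique")
        if set(values.columns) != set(samples.index):
            raise ValueError("expression columns and sample sheet disagree")
        if not np.isfinite(values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        self.values = values.loc[:, list(samples.index)].astype(float)
        self.samples = samples.copy()

    # -- basic views -----------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def linear(self) -> pd.DataFrame:
        """Linear-scale expression 2**log2 (the scale of the <=30 filter)."""
        return 2.0 ** self.values

    # -- grouping helpers ------------------------------------------------
    def cells(self) -> list[tuple[str, str]]:
        """Ordered (genotype, stage) cells, in sample-sheet order."""
        seen: list[tuple[str, str]] = []
        for _, row in self.samples.iterrows():
            cell = (row["genotype"], row["stage"])
            if cell not in seen:
                seen.append(cell)
        return seen

    def samples_in_cell(self, genotype: str, stage: str) -> list[str]:
        mask = (self.samples["genotype"] == genotype) & (
            self.samples["stage"] == stage
        )
        return list(self.samples.index[mask])

    def cell_means(self) -> pd.DataFrame:
        """Replicate-averaged log2 expression, one column per cell.

        Columns are labelled ``genotype:stage`` in sample-sheet order; this
        is the "averaged" matrix the dominant-pattern stages consume.
        """
        cols = {}
        for genotype, stage in self.cells():
            ids = self.samples_in_cell(genotype, stage)
            cols[f"{genotype}:{stage}"] = self.values[ids].mean(axis=1)
        return pd.DataFrame(cols, index=self.values.index)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.samples)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[list(sample_ids)], self.samples.loc[list(sample_ids)]
        )


@dataclass
class FuzzyPartition:
    """Soft clustering result: membership rows sum to one."""

    membership: pd.DataFrame  # genes x clusters
    objective: float
    n_iter: int
    converged: bool = True

    def __post_init__(self) -> None:
        u = self.membership.to_numpy(dtype=float)
        if (u < -1e-12).any():
            raise ValueError("memberships must be non-negative")
        if not np.allclose(u.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("membership rows must sum to 1")


@dataclass
class DominantPatternSet:
    """Merged expression prototypes plus correlation-gated gene assignments.

    ``prototypes``: pattern id -> profile over ordered cells (DataFrame,
    patterns x cells).  ``assignments``: DataFrame indexed by gene with
    columns ``pattern`` (nullable) and ``r``.  ``provenance``: pattern id ->
    list of raw cluster labels merged into it.
    """

    prototypes: pd.DataFrame
    assignments: pd.DataFrame = field(default_factory=pd.DataFrame)
    provenance: dict = field(default_factory=dict)

    @property
    def n_patterns(self) -> int:
        return self.prototypes.shape[0]

    def pattern_sizes(self) -> pd.Series:
        if self.assignments.empty:
            return pd.Series(dtype=int)
        assigned = self.assignments.dropna(subset=["pattern"])
        return assigned["pattern"].value_counts().sort_index()
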
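"""Synthetic planted-truth data generator.

Emulates the input side of a two-genotype somatic-embryogenesis microarray
study: 2 genotypes (wild type and an ascorbate-deficient *vtc2* mutant) x 4
developmental stages (bent-cotyledon zygotic embryo, day-7 induction,
day-14 induction, mature somatic embryo) x 2 biological replicates = 16
arrays, each gene measured by a probe set of perfect-match / mismatch
(PM/MM) pairs.

The generator plants, and records as ground truth: dominant expression
patterns (well-separated prototype profiles over the genotype x stage
cells), per-stage differentially expressed genes with a fixed log2 effect,
"absent" transcripts whose MM intensities track their PM intensities, GO
terms enriched in planted gene groups, promoter motifs planted as exact
IUPAC consensus sites, and a TF -> motif map.  Every downstream pipeline
stage can therefore be scored against known truth without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, ProbeIntensityTable
from .motifs import iupac_regex, sample_iupac_realization, scan_sequence

DEFAULT_STAGES = ("bent_cotyledon", "D7I", "D14I", "mature_SE")

# Synthetic consensus motifs: an Evening-Element-like nonamer and a
# homeobox-binding-site-like nonamer.  Sequence content is arbitrary; only
# their planted placement matters.
DEFAULT_MOTIFS = {"motif_EE": "AAAATATCT", "motif_HB": "CAATTATTA"}


# ---------------------------------------------------------------------------
# design and truth containers
# ---------------------------------------------------------------------------

@dataclass
class StudyDesign:
    """Factorial array design: genotypes x stages x replicates."""

    genotypes: tuple[str, ...] = ("WT", "vtc2")
    stages: tuple[str, ...] = DEFAULT_STAGES
    replicates_per_cell: int = 2
    n_genes: int = 22810
    n_probes_per_set: int = 11
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.replicates_per_cell < 2:
            raise ValueError("replicates_per_cell must be >= 2")
        if self.n_probes_per_set < 1:
            raise ValueError("n_probes_per_set must be >= 1")
        if not self.genotypes or not self.stages:
            raise ValueError("genotypes and stages must be non-empty")

    @property
    def n_samples(self) -> int:
        return len(self.genotypes) * len(self.stages) * self.replicates_per_cell

    def cells(self) -> list[tuple[str, str]]:
        return [(g, s) for g in self.genotypes for s in self.stages]

    def cell_labels(self) -> list[str]:
        return [f"{g}:{s}" for g, s in self.cells()]

    def sample_sheet(self) -> pd.DataFrame:
        rows = []
        for genotype, stage in self.cells():
            for rep in range(1, self.replicates_per_cell + 1):
                rows.append(
                    {
                        "sample_id": f"{genotype}_{stage}_r{rep}",
                        "genotype": genotype,
                        "stage": stage,
                        "replicate": rep,
                    }
                )
        return pd.DataFrame(rows).set_index("sample_id")

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]


@dataclass
class TruthConfig:
    """Knobs for what gets planted; defaults are the study-like conditions."""

    n_patterns: int = 13
    genes_per_pattern: int = 40
    pattern_max_r: float = 0.5
    genotype_symmetric_patterns: bool = False
    amplitude_range: tuple[float, float] = (1.0, 2.0)
    n_de_up_per_stage: int = 12
    n_de_down_per_stage: int = 8
    de_effect: float = 3.0
    n_absent_genes: int = 50
    baseline_range: tuple[float, float] = (6.0, 10.0)
    absent_baseline_range: tuple[float, float] = (2.0, 4.0)
    probe_affinity_sd: float = 0.7
    probe_noise_sd: float = 0.2
    replicate_sd: float = 0.15
    mm_attenuation: float = 0.3

    def __post_init__(self) -> None:
        if self.probe_noise_sd < 0 or self.replicate_sd < 0:
            raise ValueError("noise SD (probe_noise_sd / replicate_sd) must be >= 0")
        if self.de_effect < 1.0:
            raise ValueError("de_effect must be >= 1 log2 unit")
        if not 0 < self.mm_attenuation < 1:
            raise ValueError("mm_attenuation must be in (0, 1)")


@dataclass
class PlantedTruth:
    """Ground truth planted by the generator, JSON-serializable."""

    pattern_assignments: dict[str, str] = field(default_factory=dict)
    pattern_prototypes: dict[str, list[float]] = field(default_factory=dict)
    cell_labels: list[str] = field(default_factory=list)
    de_genes: dict[str, dict[str, float]] = field(default_factory=dict)
    absent_genes: list[str] = field(default_factory=list)
    enriched_terms: dict[str, list[str]] = field(default_factory=dict)
    planted_motifs: dict[str, list[str]] = field(default_factory=dict)
    tf_map: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PlantedTruth":
        return cls(**d)

    def pattern_genes(self, pattern_id: str) -> list[str]:
        return [g for g, p in self.pattern_assignments.items() if p == pattern_id]


@dataclass
class SyntheticDataset:
    """Everything one seeded simulation produced."""

    design: StudyDesign
    config: TruthConfig
    truth: PlantedTruth
    probes: ProbeIntensityTable
    gene_means: pd.DataFrame  # planted log2 mean, genes x cell labels
    annotations: dict = field(default_factory=dict)

    def true_expression(self) -> ExpressionMatrix:
        """Noise-free gene-level matrix expanded to one column per array."""
        samples = self.design.sample_sheet()
        cols = {
            sid: self.gene_means[f"{row['genotype']}:{row['stage']}"]
            for sid, row in samples.iterrows()
        }
        return ExpressionMatrix(pd.DataFrame(cols), samples)


# ---------------------------------------------------------------------------
# prototype construction
# ---------------------------------------------------------------------------

def well_separated_profiles(
    n_profiles: int,
    n_cells: int,
    max_r: float = 0.5,
    seed: int = 0,
    n_iter: int = 4000,
) -> np.ndarray:
    """Standardized profiles (mean 0, SD 1 per row) with pairwise Pearson r
    below ``max_r``, found by repulsion on the centered unit sphere.

    The bound is one-sided: strongly anticorrelated prototypes (mirror
    patterns) are distinct patterns and are allowed.  Raises if the
    requested separation cannot be reached, which happens when
    ``n_profiles`` exceeds what the (n_cells - 1)-dimensional centered
    space can accommodate at that correlation bound.
    """
    if n_cells < 2:
        raise ValueError("need at least 2 cells for a profile")
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n_profiles, n_cells))
    margin = min(0.04, max_r / 4)

    def _project(x):
        x = x - x.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(x, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return x / norms

    v = _project(v)
    target = max_r - margin
    step = 0.2
    for _ in range(n_iter):
        corr = v @ v.T
        np.fill_diagonal(corr, -1.0)
        if corr.max() < target:
            break
        # push apart pairs whose r exceeds the target
        excess = np.where(corr > target, corr, 0.0)
        grad = excess @ v
        v = _project(v - step * grad)
    corr = v @ v.T
    np.fill_diagonal(corr, -1.0)
    if corr.max() >= max_r:
        raise ValueError(
            f"could not place {n_profiles} profiles over {n_cells} cells "
            f"with pairwise |r| < {max_r}"
        )
    # rescale rows to sample SD 1 (ddof=1) so amplitudes read in log2 units
    return v * np.sqrt(n_cells - 1)


# ---------------------------------------------------------------------------
# gene-level planted means
# ---------------------------------------------------------------------------

def _assign_roles(design: StudyDesign, config: TruthConfig, rng):
    genes = design.gene_ids()
    n_pattern = config.n_patterns * config.genes_per_pattern
    n_de = (config.n_de_up_per_stage + config.n_de_down_per_stage) * len(design.stages)
    needed = n_pattern + n_de + config.n_absent_genes
    if needed > design.n_genes:
        raise ValueError(
            f"n_genes={design.n_genes} too small for planted roles ({needed} needed)"
        )
    order = rng.permutation(len(genes))
    shuffled = [genes[i] for i in order]
    pattern_genes = shuffled[:n_pattern]
    de_pool = shuffled[n_pattern : n_pattern + n_de]
    absent = shuffled[n_pattern + n_de : n_pattern + n_de + config.n_absent_genes]
    return pattern_genes, de_pool, absent


def plant_gene_means(
    design: StudyDesign, config: TruthConfig, rng
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Build the planted log2 mean matrix (genes x cells) and its truth."""
    genes = design.gene_ids()
    cells = design.cell_labels()
    n_cells = len(cells)
    truth = PlantedTruth(cell_labels=cells)

    baseline = rng.uniform(*config.baseline_range, size=design.n_genes)
    means = pd.DataFrame(
        np.tile(baseline[:, None], (1, n_cells)), index=genes, columns=cells
    )

    pattern_genes, de_pool, absent = _assign_roles(design, config, rng)

    # dominant patterns
    if config.n_patterns > 0:
        if config.genotype_symmetric_patterns:
            protos_stage = well_separated_profiles(
                config.n_patterns,
                len(design.stages),
                config.pattern_max_r,
                seed=int(rng.integers(2**31)),
            )
            protos = np.tile(protos_stage, (1, len(design.genotypes)))
        else:
            protos = well_separated_profiles(
                config.n_patterns,
                n_cells,
                config.pattern_max_r,
                seed=int(rng.integers(2**31)),
            )
        for p in range(config.n_patterns):
            pid = f"DP{p + 1}"
            truth.pattern_prototypes[pid] = list(map(float, protos[p]))
            members = pattern_genes[
                p * config.genes_per_pattern : (p + 1) * config.genes_per_pattern
            ]
            amps = rng.uniform(*config.amplitude_range, size=len(members))
            for g, amp in zip(members, amps):
                means.loc[g] = means.loc[g] + amp * protos[p]
                truth.pattern_assignments[g] = pid

    # per-stage differential genes (second genotype vs first)
    geno_b = design.genotypes[1] if len(design.genotypes) > 1 else None
    if geno_b is not None:
        idx = 0
        for stage in design.stages:
            planted: dict[str, float] = {}
            for _ in range(config.n_de_up_per_stage):
                g = de_pool[idx]
                idx += 1
                means.loc[g, f"{geno_b}:{stage}"] += config.de_effect
                planted[g] = config.de_effect
            for _ in range(config.n_de_down_per_stage):
                g = de_pool[idx]
                idx += 1
                means.loc[g, f"{geno_b}:{stage}"] -= config.de_effect
                planted[g] = -config.de_effect
            truth.de_genes[stage] = planted

    # absent transcripts sit near the noise floor
    low = rng.uniform(*config.absent_baseline_range, size=len(absent))
    for g, b in zip(absent, low):
        means.loc[g] = b
    truth.absent_genes = list(absent)

    return means, truth


# ---------------------------------------------------------------------------
# probe-level intensities
# ---------------------------------------------------------------------------

def generate_probe_intensities(
    design: StudyDesign, config: TruthConfig | None = None
) -> SyntheticDataset:
    """Simulate the PM/MM probe table for the full factorial design.

    PM intensities are lognormal around the planted per-array mean: on the
    log2 scale, PM = planted mean + probe affinity (shared across arrays,
    median-centered to zero) + replicate effect + probe noise.  MM tracks
    PM times an attenuation factor for expressed genes and equals PM (up to
    noise) for planted-absent genes, which is what drives the downstream
    Present/Absent calls.
    """
    config = config or TruthConfig()
    rng = np.random.default_rng(design.seed)
    means, truth = plant_gene_means(design, config, rng)

    samples = design.sample_sheet()
    genes = design.gene_ids()
    n_probes = design.n_probes_per_set
    n_samples = len(samples)
    absent = set(truth.absent_genes)

    # probe affinities: shared across arrays, exactly median-zero per gene
    phi = rng.normal(0.0, config.probe_affinity_sd, size=(len(genes), n_probes))
    phi = phi - np.median(phi, axis=1, keepdims=True)

    cell_of_sample = [f"{r['genotype']}:{r['stage']}" for _, r in samples.iterrows()]
    mu_cells = means[cell_of_sample].to_numpy()  # genes x samples
    rep_noise = rng.normal(0.0, config.replicate_sd, size=mu_cells.shape) \
        if config.replicate_sd > 0 else np.zeros_like(mu_cells)
    mu_arrays = mu_cells + rep_noise

    log_pm = (
        mu_arrays[:, None, :]
        + phi[:, :, None]
        + (
            rng.normal(0.0, config.probe_noise_sd, size=(len(genes), n_probes, n_samples))
            if config.probe_noise_sd > 0
            else 0.0
        )
    )
    pm = 2.0**log_pm

    mm_noise = (
        rng.normal(0.0, config.probe_noise_sd, size=pm.shape)
        if config.probe_noise_sd > 0
        else np.zeros_like(pm)
    )
    absent_mask = np.array([g in absent for g in genes])
    att = np.where(absent_mask, 1.0, config.mm_attenuation)
    mm = pm * att[:, None, None] * 2.0**mm_noise

    sample_ids = list(samples.index)
    frame = pd.DataFrame(
        {
            "probe_set_id": np.repeat(genes, n_probes * n_samples),
            "probe_index": np.tile(np.repeat(np.arange(n_probes), n_samples), len(genes)),
            "sample_id": np.tile(sample_ids, len(genes) * n_probes),
            "PM": pm.ravel(),
            "MM": mm.ravel(),
        }
    )
    table = ProbeIntensityTable(data=frame, samples=samples)
    return SyntheticDataset(
        design=design, config=config, truth=truth, probes=table, gene_means=means
    )


# ---------------------------------------------------------------------------
# annotations: GMT, promoters, motifs, TF map
# ---------------------------------------------------------------------------

@dataclass
class AnnotationConfig:
    promoter_length: int = 1000
    motifs: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_MOTIFS))
    motif_target_patterns: tuple[str, ...] = ("DP1", "DP2")
    motif_plant_fraction: float = 0.9
    tf_counts: tuple[int, ...] = (1, 5)
    term_fraction: float = 0.75
    n_background_terms: int = 20
    background_term_size: int = 20

    def __post_init__(self) -> None:
        for motif_id, consensus in self.motifs.items():
            iupac_regex(consensus)  # raises on non-IUPAC characters
            if self.promoter_length < len(consensus):
                raise ValueError(
                    f"promoter length {self.promoter_length} shorter than "
                    f"motif {motif_id}"
                )


def _stratified_background_term(groups: list[list[str]], size: int, rng) -> list[str]:
    """Sample a term spread proportionally over gene groups.

    Proportional allocation keeps the overlap of a background term with any
    planted group at its expected value, so background terms are
    non-enriched by construction rather than merely on average.
    """
    total = sum(len(g) for g in groups)
    counts = [int(round(size * len(g) / total)) for g in groups]
    # absorb rounding drift into the largest group
    drift = size - sum(counts)
    counts[int(np.argmax([len(g) for g in groups]))] += drift
    members: list[str] = []
    for group, k in zip(groups, counts):
        k = max(0, min(k, len(group)))
        idx = rng.choice(len(group), size=k, replace=False)
        members.extend(group[i] for i in sorted(idx))
    return members


def generate_annotations(
    dataset: SyntheticDataset, config: AnnotationConfig | None = None
) -> dict:
    """Plant GO terms, promoters with motif sites, and the TF map.

    Returns a dict with keys ``gmt`` (term id -> description/genes),
    ``promoters`` (gene -> sequence), ``motifs`` (motif id -> consensus) and
    ``tf_map`` (TF gene -> motif id); also stored on ``dataset.annotations``
    and reflected into ``dataset.truth``.
    """
    config = config or AnnotationConfig()
    truth = dataset.truth
    rng = np.random.default_rng(dataset.design.seed + 1)
    genes = dataset.design.gene_ids()

    # --- GO terms --------------------------------------------------------
    gmt: dict[str, dict] = {}
    pattern_ids = sorted({p for p in truth.pattern_assignments.values()},
                         key=lambda s: int(s[2:]))
    for i, pid in enumerate(pattern_ids, start=1):
        members = truth.pattern_genes(pid)
        size = max(1, int(round(config.term_fraction * len(members))))
        idx = rng.choice(len(members), size=size, replace=False)
        term_id = f"GO:{7000000 + i}"
        gmt[term_id] = {
            "description": f"planted process of {pid}",
            "genes": [members[j] for j in sorted(idx)],
        }
        truth.enriched_terms.setdefault(pid, []).append(term_id)

    grouped = [truth.pattern_genes(pid) for pid in pattern_ids]
    assigned = set(truth.pattern_assignments)
    rest = [g for g in genes if g not in assigned]
    groups = [g for g in grouped if g] + ([rest] if rest else [])
    for i in range(config.n_background_terms):
        term_id = f"GO:{8000000 + i + 1}"
        gmt[term_id] = {
            "description": "background process",
            "genes": _stratified_background_term(
                groups, config.background_term_size, rng
            ),
        }

    # --- promoters and motif sites --------------------------------------
    motifs = dict(config.motifs)
    planted_in: dict[str, list[str]] = {m: [] for m in motifs}
    motif_ids = list(motifs)
    for pid, motif_id in zip(config.motif_target_patterns, motif_ids):
        members = truth.pattern_genes(pid)
        n_hit = int(round(config.motif_plant_fraction * len(members)))
        idx = rng.choice(len(members), size=n_hit, replace=False)
        planted_in[motif_id] = [members[j] for j in sorted(idx)]

    carriers = {g: m for m, gl in planted_in.items() for g in gl}
    bases = np.array(list("ACGT"))
    promoters: dict[str, str] = {}
    consensi = list(motifs.values())
    for g in genes:
        while True:
            seq = "".join(rng.choice(bases, size=config.promoter_length))
            if all(scan_sequence(seq, c) == 0 for c in consensi):
                break
        if g in carriers:
            consensus = motifs[carriers[g]]
            site = sample_iupac_realization(consensus, rng)
            pos = int(rng.integers(0, config.promoter_length - len(site) + 1))
            seq = seq[:pos] + site + seq[pos + len(site):]
        promoters[g] = seq
    truth.planted_motifs = {m: list(gl) for m, gl in planted_in.items()}

    # --- TF map ----------------------------------------------------------
    tf_map: dict[str, str] = {}
    for (pid, motif_id), n_tf in zip(
        zip(config.motif_target_patterns, motif_ids), config.tf_counts
    ):
        members = truth.pattern_genes(pid)
        hit = set(planted_in[motif_id])
        # TFs are co-regulated members of the same pattern; prefer motif
        # carriers so the TF also appears among the module's targets
        candidates = [g for g in members if g in hit] + [
            g for g in members if g not in hit
        ]
        for g in candidates[:n_tf]:
            tf_map[g] = motif_id
    truth.tf_map = dict(tf_map)

    annotations = {
        "gmt": gmt,
        "promoters": promoters,
        "motifs": motifs,
        "tf_map": tf_map,
    }
    dataset.annotations = annotations
    return annotations


# ---------------------------------------------------------------------------
# qPCR fixture
# ---------------------------------------------------------------------------

def generate_qpcr_table(
    expression: pd.DataFrame,
    reference_gene: str,
    seed: int = 0,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    base_ct: float = 32.0,
) -> pd.DataFrame:
    """Simulate a Ct table from log2 expression (genes x conditions).

    Ct = base - log2(expression) + noise, so planted fold changes are
    recovered by the 2^-ddCt arithmetic.  The reference gene must be a row
    of ``expression`` (typically planted flat across conditions).
    """
    if reference_gene not in expression.index:
        raise ValueError(f"reference gene {reference_gene!r} missing from table")
    rng = np.random.default_rng(seed)
    rows = []
    for condition in expression.columns:
        for gene in expression.index:
            for rep in range(1, n_replicates + 1):
                ct = base_ct - expression.loc[gene, condition]
                if noise_sd > 0:
                    ct += rng.normal(0.0, noise_sd)
                rows.append(
                    {
                        "sample": f"{condition}_r{rep}",
                        "condition": condition,
                        "gene": gene,
                        "Ct": ct,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gene-level fixture for statistical calibration
# ---------------------------------------------------------------------------

def simulate_gene_matrix(
    design: StudyDesign,
    effects: dict[str, dict[str, float]] | None = None,
    sd: float = 0.25,
    baseline_range: tuple[float, float] = (6.0, 10.0),
    seed: int = 0,
) -> ExpressionMatrix:
    """Gene-level log2 matrix with additive Gaussian noise.

    ``effects``: stage -> {gene: log2 shift applied to the second genotype}.
    With ``effects=None`` this is a complete-null dataset (all genes
    exchangeable across genotypes).
    """
    rng = np.random.default_rng(seed)
    genes = design.gene_ids()
    samples = design.sample_sheet()
    base = rng.uniform(*baseline_range, size=len(genes))
    values = pd.DataFrame(
        np.tile(base[:, None], (1, len(samples))), index=genes, columns=samples.index
    )
    if effects:
        geno_b = design.genotypes[1]
        for stage, shifts in effects.items():
            cols = [
                sid
                for sid, row in samples.iterrows()
                if row["genotype"] == geno_b and row["stage"] == stage
            ]
            for gene, delta in shifts.items():
                values.loc[gene, cols] += delta
    if sd > 0:
        values = values + rng.normal(0.0, sd, size=values.shape)
    return ExpressionMatrix(values, samples)
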
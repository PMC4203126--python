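"""Shared planted-pattern recovery harness used by pattern and acceptance tests."""

import numpy as np
import pandas as pd

from embryoarray.patterns import (
    assign_genes,
    core_genes,
    fanny_cluster,
    merge_clusters,
    standardize_profiles,
)
from embryoarray.simulate import well_separated_profiles


def planted_profiles(n_patterns, n_cells, seed, genes_per=40, noise_sd=0.2,
                     max_r=0.5):
    """Gene profiles built as amplitude-scaled prototypes plus Gaussian noise."""
    protos = well_separated_profiles(n_patterns, n_cells, max_r, seed=seed)
    rng = np.random.default_rng(seed + 1000)
    rows, labels = [], []
    for p in range(n_patterns):
        amps = rng.uniform(1.0, 2.0, genes_per)
        for amp in amps:
            rows.append(amp * protos[p] + rng.normal(0, noise_sd, n_cells))
            labels.append(p)
    profiles = pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))])
    return protos, profiles, labels


def run_recovery(n_patterns, n_cells, seed, genes_per=40, noise_sd=0.2, k=15):
    """Full DP procedure on planted data -> (pattern count, assignment accuracy)."""
    protos, raw, labels = planted_profiles(
        n_patterns, n_cells, seed, genes_per, noise_sd
    )
    profiles = standardize_profiles(raw)
    partition = fanny_cluster(profiles, k=min(k, profiles.shape[0]), seed=seed + 2)
    cores, prototypes = core_genes(partition, profiles, m=0.44)
    sizes = {c: len(g) for c, g in cores.items()}
    merged = merge_clusters(prototypes, sizes=sizes, merge_r=0.90)
    result = assign_genes(profiles, merged, r_min=0.85)

    pz = (protos - protos.mean(1, keepdims=True)) / protos.std(1, keepdims=True)
    mp = merged.prototypes.to_numpy()
    mz = (mp - mp.mean(1, keepdims=True)) / mp.std(1, keepdims=True)
    match_corr = pz @ mz.T / n_cells
    match = {
        p: merged.prototypes.index[int(np.argmax(match_corr[p]))]
        for p in range(n_patterns)
    }
    correct = [
        result.assignments.loc[g, "pattern"] == match[lab]
        for g, lab in zip(profiles.index, labels)
    ]
    return merged.n_patterns, float(np.mean(correct))
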
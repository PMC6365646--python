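"""Shared fixture builders and independent oracles used across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd

from fitcaller import synthdata

PATHWAY_SIZE = 13
N_DECOYS = 6
N_FOCAL = 6
N_BACKGROUND = 120  # 12 background conditions x 10 replicates


def make_pathway_dataset(
    seed: int,
    planted: bool = True,
    depth: int = 2_000_000,
    n_genes: int = 1000,
    n_strains: int = 15000,
    effect: float = -2.0,
):
    """Planted-pathway dataset: 6 focal + 120 background experiments.

    13 pathway genes carry ``effect`` in every focal experiment; 6 decoy genes
    carry it in exactly one focal experiment (a single-experiment artifact the
    consistency filter must reject). The focal share is 6/126 = 4.8%, matching
    the regime of a real multi-condition compendium.
    """
    genome = synthdata.generate_genome(1, n_genes, 900, 0.5, seed=seed)
    pool, baseline = synthdata.generate_pool(genome, n_strains, seed=seed + 1)
    tags = genome.locus_tags
    pathway = tags[10 : 10 + PATHWAY_SIZE]
    decoys = tags[40 : 40 + N_DECOYS]

    if planted:
        effects = {
            "deoxyribose": [(lt, effect) for lt in pathway],
            "deoxyribose_artifact": [(lt, effect) for lt in pathway + decoys],
        }
    else:
        effects = {}
    truth = synthdata.plant_effects(genome, effects, baseline=baseline)

    rows = [
        {"sample": f"T0_{i}", "condition": "Time0", "t0set": "T0A", "is_time0": True,
         "truth_condition": None}
        for i in (1, 2)
    ]
    for j in range(N_FOCAL):
        rows.append(
            {"sample": f"dxr_{j}", "condition": "deoxyribose", "t0set": "T0A",
             "is_time0": False,
             "truth_condition": "deoxyribose_artifact" if j == N_FOCAL - 1 else None}
        )
    for c in range(N_BACKGROUND // 10):
        for j in range(10):
            rows.append(
                {"sample": f"c{c}_{j}", "condition": f"c{c}", "t0set": "T0A",
                 "is_time0": False, "truth_condition": None}
            )
    samples = pd.DataFrame(rows)
    counts = synthdata.build_count_table(pool, truth, samples, depth, seed=seed + 2)
    return {
        "genome": genome,
        "pool": pool,
        "truth": truth,
        "counts": counts,
        "pathway": pathway,
        "decoys": decoys,
        "focal_experiments": [f"dxr_{j}" for j in range(N_FOCAL)],
        "effect": effect,
    }


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_kde_mode(values: np.ndarray, grid_step: float = 0.01) -> float:
    """Gaussian-KDE mode by direct summation with the Silverman-rule bandwidth.

    Written from the definition (sum of Gaussians, h = sd * (3n/4)^(-1/5))
    rather than via scipy, to serve as an oracle for mode normalization.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    n = len(values)
    h = values.std(ddof=1) * (3.0 * n / 4.0) ** (-0.2)
    grid = np.arange(values.min(), values.max() + grid_step, grid_step)
    dens = np.exp(-0.5 * ((grid[:, None] - values[None, :]) / h) ** 2).sum(axis=1)
    return float(grid[np.argmax(dens)])


def oracle_specific(F: pd.DataFrame, T: pd.DataFrame, percentile: float):
    """Re-derive every specific-phenotype call from the emitted tables.

    One-line-per-criterion evaluation of: fitness < -1, t < -5, >=95% of the
    gene's fitness values in (-1, 1), |fitness| > percentile(|fitness|) + 0.5.
    Returns a set of (locus_tag, experiment) pairs.
    """
    hits = set()
    for locus in F.index:
        f_row = F.loc[locus].to_numpy(float)
        t_row = T.loc[locus].to_numpy(float)
        finite = f_row[np.isfinite(f_row)]
        if len(finite) == 0 or (len(finite) / len(f_row)) <= 0.5:
            continue
        band_ok = np.mean((finite > -1) & (finite < 1)) >= 0.95
        thresh = np.percentile(np.abs(finite), percentile) + 0.5
        for exp, f, t in zip(F.columns, f_row, t_row):
            if np.isfinite(f) and f < -1 and t < -5 and band_ok and abs(f) > thresh:
                hits.add((locus, exp))
    return hits
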
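"""Strain fitness, weighted gene fitness and per-experiment mode normalization.

The fitness of a strain is the normalized log2 ratio of its barcode's reads
in a post-growth sample versus the paired Time0 control(s); the fitness of a
gene is an inverse-variance weighted average over strains inserted in the
central portion of the gene, shifted so that the kernel-density mode of each
experiment's gene-fitness distribution sits at zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .bcio import CountTable
from .errors import DegenerateInputError, InvalidParameterError, PairingError

LN2_SQ = math.log(2.0) ** 2


@dataclass(frozen=True)
class FitnessParams:
    """Tunable constants of the fitness estimator.

    pseudocount keeps zero-count strains finite; central_window restricts
    gene fitness to insertions in the central part of the gene (default
    10-90% of its length); strains with fewer than min_t0_reads reads in the
    summed Time0 controls are excluded as insufficiently abundant.
    """

    pseudocount: float = 0.5
    central_window: tuple[float, float] = (0.1, 0.9)
    min_t0_reads: int = 3
    mode_grid_step: float = 0.01
    kde_bandwidth_rule: str = "silverman"

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise InvalidParameterError("pseudocount must be > 0")
        lo, hi = self.central_window
        if not (0 <= lo < hi <= 1):
            raise InvalidParameterError("central_window must satisfy 0 <= low < high <= 1")
        if self.mode_grid_step <= 0:
            raise InvalidParameterError("mode_grid_step must be > 0")


@dataclass
class FitnessMatrix:
    """Gene x experiment fitness estimates and their bookkeeping.

    All frames share the same index (locus_tags) and columns (experiment
    ids). Cells with no usable strain are NaN (absent), never 0. ``shifts``
    records the per-experiment mode shift that was subtracted.
    """

    fitness: pd.DataFrame
    n_strains: pd.DataFrame
    var_counts: pd.DataFrame
    var_emp: pd.DataFrame
    shifts: pd.Series


# ---------------------------------------------------------------------------
# strain fitness
# ---------------------------------------------------------------------------

def strain_fitness(
    counts: CountTable, experiment: str, params: FitnessParams = FitnessParams()
) -> pd.DataFrame:
    """Per-strain normalized log2 ratios for one experiment.

    With n_a, n_0 a strain's reads in the experiment and in the summed Time0
    samples of its t0set, and N_a, N_0 the corresponding sample totals:

        f_s = log2((n_a + psi) / N_a) - log2((n_0 + psi) / N_0)

    Returns a frame indexed by barcode with columns fitness, n_after, n_t0,
    sufficient; strains with n_0 < min_t0_reads are flagged insufficient and
    carry NaN fitness.
    """
    row = counts.sample_row(experiment)
    if row["is_time0"]:
        raise PairingError(f"{experiment!r} is a Time0 sample, not an experiment")
    t0_ids = counts.time0_samples(row["t0set"])
    if not t0_ids:
        raise PairingError(f"no Time0 samples for t0set {row['t0set']!r}")

    n_a = counts.counts[experiment].to_numpy(float)
    n_0 = counts.counts[t0_ids].sum(axis=1).to_numpy(float)
    N_a, N_0 = n_a.sum(), n_0.sum()
    if N_a <= 0 or N_0 <= 0:
        raise DegenerateInputError("zero-total sample")

    psi = params.pseudocount
    f = np.log2((n_a + psi) / N_a) - np.log2((n_0 + psi) / N_0)
    sufficient = n_0 >= params.min_t0_reads
    f = np.where(sufficient, f, np.nan)
    return pd.DataFrame(
        {"fitness": f, "n_after": n_a, "n_t0": n_0, "sufficient": sufficient},
        index=counts.counts.index,
    )


# ---------------------------------------------------------------------------
# gene fitness
# ---------------------------------------------------------------------------

def strain_variance(n_after: np.ndarray, n_t0: np.ndarray) -> np.ndarray:
    """Count-based variance of a strain's log2 ratio (delta-method form)."""
    return (1.0 / (1.0 + n_after) + 1.0 / (1.0 + n_t0)) / LN2_SQ


def gene_fitness(
    strain_fit: pd.DataFrame,
    pool: pd.DataFrame,
    params: FitnessParams = FitnessParams(),
) -> pd.DataFrame:
    """Inverse-variance weighted gene fitness over central insertions.

    Only strains that hit a gene, at a within-gene fraction inside
    ``central_window`` (inclusive), with sufficient Time0 reads, contribute.
    Weights are w_s = 1 / v_s with v_s from :func:`strain_variance`.

    Returns a frame indexed by locus_tag with columns fitness_raw, n_strains,
    var_counts (1 / sum of weights) and var_emp (weighted sample variance of
    the strain fitnesses divided by n_strains; NaN when n_strains < 2).
    """
    lo, hi = params.central_window
    merged = pool.merge(
        strain_fit, left_on="barcode", right_index=True, how="inner", validate="1:1"
    )
    usable = (
        merged["locus_tag"].notna()
        & merged["fraction"].between(lo, hi, inclusive="both")
        & merged["sufficient"]
    )
    merged = merged[usable]

    if merged.empty:
        return pd.DataFrame(
            columns=["fitness_raw", "n_strains", "var_counts", "var_emp"]
        ).rename_axis("locus_tag")

    w = 1.0 / strain_variance(merged["n_after"].to_numpy(), merged["n_t0"].to_numpy())
    f = merged["fitness"].to_numpy()
    df = pd.DataFrame({"locus_tag": merged["locus_tag"].to_numpy(), "w": w, "wf": w * f, "f": f})
    grouped = df.groupby("locus_tag", sort=True)
    sum_w = grouped["w"].sum()
    fit = grouped["wf"].sum() / sum_w
    n = grouped.size()

    # weighted sample variance about the weighted mean, with an n/(n-1)
    # small-sample correction, then scaled to the variance of the mean
    df["dev2w"] = df["w"] * (df["f"] - fit.reindex(df["locus_tag"]).to_numpy()) ** 2
    wvar = df.groupby("locus_tag", sort=True)["dev2w"].sum() / sum_w
    with np.errstate(divide="ignore", invalid="ignore"):
        var_emp = wvar * n / (n - 1) / n
    var_emp[n < 2] = np.nan

    return pd.DataFrame(
        {
            "fitness_raw": fit,
            "n_strains": n,
            "var_counts": 1.0 / sum_w,
            "var_emp": var_emp,
        }
    ).rename_axis("locus_tag")


# ---------------------------------------------------------------------------
# mode normalization
# ---------------------------------------------------------------------------

def normalize_mode(
    values, params: FitnessParams = FitnessParams()
) -> tuple[np.ndarray, float]:
    """Shift a gene-fitness vector so its kernel-density mode is zero.

    The mode is the argmax of a Gaussian KDE (bandwidth per
    ``kde_bandwidth_rule``) evaluated on a grid of step ``mode_grid_step``
    spanning the finite values. Fewer than 10 finite values: a warning is
    issued and the shift is 0.
    """
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size < 10:
        warnings.warn("fewer than 10 finite values; mode normalization skipped")
        return arr.copy(), 0.0
    shift = kde_mode(finite, params.mode_grid_step, params.kde_bandwidth_rule)
    return arr - shift, shift


def kde_mode(values: np.ndarray, grid_step: float = 0.01, bw_rule: str = "silverman") -> float:
    """Location of the Gaussian-KDE mode on a regular grid spanning the data."""
    values = np.asarray(values, dtype=float)
    if np.ptp(values) == 0:  # degenerate: all values identical
        return float(values[0])
    kde = gaussian_kde(values, bw_method=bw_rule)
    grid = np.arange(values.min(), values.max() + grid_step, grid_step)
    return float(grid[np.argmax(kde(grid))])


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def compute_fitness_matrix(
    counts: CountTable,
    pool: pd.DataFrame,
    params: FitnessParams = FitnessParams(),
    locus_tags: list[str] | None = None,
) -> FitnessMatrix:
    """Full gene x experiment fitness matrix with per-experiment normalization.

    ``locus_tags``, when given, fixes the row universe (genes never hit by a
    usable strain appear as NaN rows); otherwise rows are the genes observed
    in the pool.
    """
    if locus_tags is None:
        locus_tags = sorted(pool["locus_tag"].dropna().unique())
    experiments = counts.experiments

    fit = pd.DataFrame(index=pd.Index(locus_tags, name="locus_tag"), columns=experiments, dtype=float)
    n_strains = fit.copy()
    var_counts = fit.copy()
    var_emp = fit.copy()
    shifts = pd.Series(0.0, index=experiments, name="mode_shift")

    for exp in experiments:
        sf = strain_fitness(counts, exp, params)
        gf = gene_fitness(sf, pool, params)
        raw = gf["fitness_raw"].reindex(locus_tags)
        normalized, shift = normalize_mode(raw.to_numpy(), params)
        fit[exp] = normalized
        n_strains[exp] = gf["n_strains"].reindex(locus_tags)
        var_counts[exp] = gf["var_counts"].reindex(locus_tags)
        var_emp[exp] = gf["var_emp"].reindex(locus_tags)
        shifts[exp] = shift

    n_strains = n_strains.fillna(0).astype(int)
    return FitnessMatrix(
        fitness=fit, n_strains=n_strains, var_counts=var_counts, var_emp=var_emp, shifts=shifts
    )
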
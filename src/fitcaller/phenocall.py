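"""Specific-phenotype calling and downstream gene-list construction.

A gene has a *specific* phenotype in an experiment when four criteria hold
jointly: fitness < -1; t < -5; at least 95% of the gene's fitness values
across all experiments lie in (-1, 1); and |fitness| in that experiment
exceeds the Pth percentile of the gene's |fitness| across all experiments by
more than 0.5. P is 95 by default but drops to 90 when the focal conditions
make up more than 5% of the experiments, so that the percentile itself is not
dominated by focal values.

The band and percentile references include the focal experiments; see the
package docs for why a large focal share is incompatible with these criteria.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .fitness import FitnessMatrix
from .sigstats import TMatrix


@dataclass(frozen=True)
class SpecificityCriteria:
    """Thresholds of the four-part specific-phenotype rule."""

    fitness_max: float = -1.0
    t_max: float = -5.0
    band: tuple[float, float] = (-1.0, 1.0)
    band_quantile: float = 0.95
    percentile: float = 95.0
    margin: float = 0.5


@dataclass(frozen=True)
class ConsistencyRule:
    """Surrogate for the manual 'consistent fitness defect' screen.

    A gene makes the consistent list for a focal condition iff it is specific
    in at least ``min_specific_experiments`` focal experiments, has fitness
    <= -1 in at least ``fraction_below`` of the focal experiments, and has
    mean focal fitness <= ``mean_max``.
    """

    min_specific_experiments: int = 1
    fraction_below: float = 0.5
    below_threshold: float = -1.0
    mean_max: float = -1.0


# ---------------------------------------------------------------------------
# percentile selection
# ---------------------------------------------------------------------------

def focal_share(metadata: pd.DataFrame, focal_conditions: Iterable[str]) -> float:
    """Fraction of (non-Time0) experiments whose condition is focal."""
    if "is_time0" in metadata.columns:
        experiments = metadata[~metadata["is_time0"]]
    else:
        experiments = metadata
    if len(experiments) == 0:
        raise ValidationError("no experiments in metadata")
    focal = experiments["condition"].isin(set(focal_conditions))
    return float(focal.sum()) / len(experiments)


def focal_share_percent(metadata: pd.DataFrame, focal_conditions: Iterable[str]) -> int:
    """Focal share as a percentage rounded to the nearest integer."""
    return round(focal_share(metadata, focal_conditions) * 100)


def choose_percentile(
    metadata: pd.DataFrame, focal_conditions: Iterable[str], switch_share: float = 0.05
) -> float:
    """95th percentile normally; 90th when focal experiments exceed ``switch_share``.

    With a large focal share, the 95th percentile of a focal-important gene's
    |fitness| lands on the focal values themselves and the specificity margin
    can never be met; dropping to the 90th percentile restores headroom.
    The switch is inclusive: a share of exactly ``switch_share`` keeps 95.
    """
    share = focal_share(metadata, focal_conditions)
    return 95.0 if share <= switch_share else 90.0


# ---------------------------------------------------------------------------
# specific-phenotype calls
# ---------------------------------------------------------------------------

CALL_COLUMNS = [
    "locus_tag",
    "experiment",
    "fitness",
    "t",
    "low_fitness",
    "low_t",
    "band_ok",
    "above_percentile",
    "specific",
]


def call_specific(
    fitness: FitnessMatrix | pd.DataFrame,
    t: TMatrix | pd.DataFrame,
    criteria: SpecificityCriteria = SpecificityCriteria(),
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Evaluate the four specificity criteria for every gene x experiment cell.

    Returns ``(calls, withheld)``. ``calls`` is long-form with one row per
    cell where fitness is present, carrying the four criterion flags and the
    overall ``specific`` flag (their AND). Genes absent in at least half of
    the experiments are withheld entirely and reported in ``withheld`` with a
    reason.
    """
    F = fitness.fitness if isinstance(fitness, FitnessMatrix) else fitness
    T = t.t if isinstance(t, TMatrix) else t
    if not (F.index.equals(T.index) and F.columns.equals(T.columns)):
        raise ValidationError("fitness and t matrices are not aligned")

    fv = F.to_numpy(float)
    tv = T.to_numpy(float)
    present = np.isfinite(fv)
    n_exp = fv.shape[1]

    withheld: dict[str, str] = {}
    keep = np.ones(len(F), dtype=bool)
    absent_frac = 1.0 - present.sum(axis=1) / n_exp
    for i, locus in enumerate(F.index):
        if absent_frac[i] >= 0.5:
            keep[i] = False
            withheld[locus] = (
                f"absent in {int(round(absent_frac[i] * n_exp))} of {n_exp} experiments"
            )

    lo_band, hi_band = criteria.band
    with np.errstate(invalid="ignore"):
        in_band = (fv > lo_band) & (fv < hi_band)
    n_present = present.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        band_frac = np.where(n_present > 0, (in_band & present).sum(axis=1) / n_present, np.nan)
    band_ok_gene = band_frac >= criteria.band_quantile

    abs_f = np.abs(fv)
    pctl = np.full(len(F), np.nan)
    rows_any = n_present > 0
    pctl[rows_any] = [
        np.nanpercentile(abs_f[i], criteria.percentile) for i in np.where(rows_any)[0]
    ]

    with np.errstate(invalid="ignore"):
        low_fitness = fv < criteria.fitness_max
        low_t = tv < criteria.t_max
        above_pct = abs_f > (pctl[:, None] + criteria.margin)
    band_ok = np.broadcast_to(band_ok_gene[:, None], fv.shape)
    specific = low_fitness & low_t & band_ok & above_pct

    gi, ei = np.where(present & keep[:, None])
    calls = pd.DataFrame(
        {
            "locus_tag": F.index.to_numpy()[gi],
            "experiment": F.columns.to_numpy()[ei],
            "fitness": fv[gi, ei],
            "t": tv[gi, ei],
            "low_fitness": low_fitness[gi, ei],
            "low_t": low_t[gi, ei],
            "band_ok": band_ok[gi, ei],
            "above_percentile": above_pct[gi, ei],
            "specific": specific[gi, ei],
        },
        columns=CALL_COLUMNS,
    )
    return calls, withheld


# ---------------------------------------------------------------------------
# consistent gene lists
# ---------------------------------------------------------------------------

def consistent_genes(
    calls: pd.DataFrame,
    fitness: FitnessMatrix | pd.DataFrame,
    metadata: pd.DataFrame,
    focal_condition: str,
    rule: ConsistencyRule = ConsistencyRule(),
) -> pd.DataFrame:
    """Genes consistently important under a focal condition, ranked by severity.

    Inclusion requires a specific call in at least
    ``rule.min_specific_experiments`` focal experiments, fitness <= -1 in at
    least ``rule.fraction_below`` of the focal experiments, and mean focal
    fitness <= ``rule.mean_max``. Returns the included genes with per-gene
    evidence, most severe (lowest mean focal fitness) first.
    """
    F = fitness.fitness if isinstance(fitness, FitnessMatrix) else fitness
    focal_exps = metadata.loc[
        (~metadata["is_time0"]) & (metadata["condition"] == focal_condition), "sample"
    ].tolist()
    if not focal_exps:
        raise ValidationError(f"no experiments for focal condition {focal_condition!r}")

    focal_calls = calls[calls["experiment"].isin(focal_exps)]
    n_specific = focal_calls.groupby("locus_tag")["specific"].sum()

    focal_F = F[focal_exps]
    n_focal = len(focal_exps)
    with np.errstate(invalid="ignore"):
        n_below = (focal_F <= rule.below_threshold).sum(axis=1)
    mean_focal = focal_F.mean(axis=1, skipna=True)

    evidence = pd.DataFrame(
        {
            "n_specific": n_specific.reindex(F.index).fillna(0).astype(int),
            "n_focal": n_focal,
            "n_below": n_below,
            "frac_below": n_below / n_focal,
            "mean_focal_fitness": mean_focal,
        }
    ).rename_axis("locus_tag")
    included = (
        (evidence["n_specific"] >= rule.min_specific_experiments)
        & (evidence["frac_below"] >= rule.fraction_below)
        & (evidence["mean_focal_fitness"] <= rule.mean_max)
    )
    return evidence[included].sort_values("mean_focal_fitness")


# ---------------------------------------------------------------------------
# cross-condition classification
# ---------------------------------------------------------------------------

def classify_conditions(
    genes: Sequence[str],
    fitness: FitnessMatrix | pd.DataFrame,
    metadata: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    important_max: float = -1.0,
    neutral_min: float = -0.5,
) -> pd.Series:
    """Label each gene by where it matters: both, A_only, B_only, or mixed.

    A gene is ``A_only`` when its mean fitness on A is at most ``important_max``
    and its mean on B is at least ``neutral_min`` (and symmetrically for
    ``B_only``); ``both`` when both means are at most ``important_max``;
    anything else is ``mixed``.
    """
    F = fitness.fitness if isinstance(fitness, FitnessMatrix) else fitness
    exps = {}
    for cond in (condition_a, condition_b):
        ids = metadata.loc[
            (~metadata["is_time0"]) & (metadata["condition"] == cond), "sample"
        ].tolist()
        if not ids:
            raise ValidationError(f"no experiments for condition {cond!r}")
        exps[cond] = ids
    unknown = [g for g in genes if g not in F.index]
    if unknown:
        raise ValidationError(f"genes not in fitness matrix: {unknown}")

    mean_a = F.loc[list(genes), exps[condition_a]].mean(axis=1)
    mean_b = F.loc[list(genes), exps[condition_b]].mean(axis=1)

    labels = []
    for a, b in zip(mean_a, mean_b):
        if a <= important_max and b <= important_max:
            labels.append("both")
        elif a <= important_max and b >= neutral_min:
            labels.append("A_only")
        elif b <= important_max and a >= neutral_min:
            labels.append("B_only")
        else:
            labels.append("mixed")
    return pd.Series(labels, index=pd.Index(genes, name="locus_tag"), name="class")
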
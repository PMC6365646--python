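"""The t-like significance statistic: fitness over the root of its estimated variance."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .fitness import FitnessMatrix

DEFAULT_V_FLOOR = 0.01


def t_statistic(f, var_counts, var_emp=None, v_floor: float = DEFAULT_V_FLOOR):
    """t = f / sqrt(max(var_counts, var_emp) + v_floor), elementwise.

    ``var_emp`` may be None/NaN (too few strains for an empirical variance),
    in which case only the count-based variance is used. Absent fitness (NaN)
    yields absent t, never 0. The floor keeps |t| finite and guards against
    underdispersed variance estimates.
    """
    if v_floor < 0:
        raise InvalidParameterError("v_floor must be nonnegative")
    f = np.asarray(f, dtype=float)
    vc = np.asarray(var_counts, dtype=float)
    if np.any(vc[np.isfinite(vc)] <= 0):
        raise InvalidParameterError("var_counts must be positive")
    if var_emp is None:
        ve = np.zeros_like(vc)
    else:
        ve = np.nan_to_num(np.asarray(var_emp, dtype=float), nan=0.0)
    denom = np.sqrt(np.maximum(vc, ve) + v_floor)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = f / denom
    if t.ndim == 0:
        return float(t)
    return t


@dataclass
class TMatrix:
    """Gene x experiment t values, aligned with a FitnessMatrix."""

    t: pd.DataFrame
    v_floor: float = DEFAULT_V_FLOOR


def t_matrix(fm: FitnessMatrix, v_floor: float = DEFAULT_V_FLOOR) -> TMatrix:
    """t statistics for every cell of a fitness matrix."""
    t = pd.DataFrame(
        t_statistic(
            fm.fitness.to_numpy(),
            fm.var_counts.to_numpy(),
            fm.var_emp.to_numpy(),
            v_floor=v_floor,
        ),
        index=fm.fitness.index,
        columns=fm.fitness.columns,
    )
    return TMatrix(t=t, v_floor=v_floor)
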
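"""Community-matrix transforms and supporting statistics.

These are the standard pre-ordination steps: lg(x+1) for abundance
matrices, Hellinger for biomass, column z-scoring for environmental
tables, Bray-Curtis dissimilarity between sampling units, Pearson
correlation of spectrum curvature against environmental variables, and
the conventional interpretation bands for NMDS stress.

Matrices are pandas DataFrames with sampling units as rows and species
(or variables) as columns.
"""

from __future__ import annotations

import enum
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

from fishspectra.errors import DegenerateInputError


def _check_nonnegative(matrix: pd.DataFrame) -> None:
    if (matrix.to_numpy() < 0).any():
        raise ValueError("matrix cells must be non-negative")


def log10_plus1(matrix: pd.DataFrame) -> pd.DataFrame:
    """Cellwise lg(x + 1); zeros stay zero."""
    _check_nonnegative(matrix)
    return np.log10(matrix + 1.0)


def hellinger(matrix: pd.DataFrame) -> pd.DataFrame:
    """Hellinger transform: sqrt of row-relative abundance.

    Each transformed row has unit sum of squares; rows must have a
    positive total.
    """
    _check_nonnegative(matrix)
    row_sums = matrix.sum(axis=1)
    zero = row_sums[row_sums <= 0]
    if len(zero):
        raise DegenerateInputError(
            f"rows with zero total: {list(zero.index)}"
        )
    return np.sqrt(matrix.div(row_sums, axis=0))


def zscore(env_table: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Columnwise standardization to mean 0, sd 1 (sample sd, ddof=1)."""
    sd = env_table.std(ddof=ddof)
    constant = sd[sd == 0]
    if len(constant):
        raise DegenerateInputError(
            f"constant column(s): {list(constant.index)}"
        )
    return (env_table - env_table.mean()) / sd


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between rows.

    d(u, v) = sum|u_i - v_i| / sum(u_i + v_i), in [0, 1]; undefined when
    two rows are both all-zero.
    """
    _check_nonnegative(matrix)
    if len(matrix) < 2:
        raise ValueError("need at least 2 rows")
    arr = matrix.to_numpy(dtype=float)
    if (arr.sum(axis=1) == 0).sum() >= 2:
        raise DegenerateInputError(
            "Bray-Curtis is undefined between two all-zero rows"
        )
    dm = squareform(pdist(arr, metric="braycurtis"))
    return pd.DataFrame(dm, index=matrix.index, columns=matrix.index)


class StressCategory(str, enum.Enum):
    CREDIBLE = "credible"
    BASICALLY_CREDIBLE = "basically credible"
    SOME_REFERENCE = "some reference significance"
    UNTRUSTWORTHY = "untrustworthy"


def stress_category(stress: float) -> StressCategory:
    """Interpretation band for an NMDS stress value.

    Half-open bands closed on the left: [0, 0.05) credible, [0.05, 0.10)
    basically credible, [0.10, 0.20) some reference significance, and
    >= 0.20 untrustworthy.
    """
    if stress < 0:
        raise ValueError("stress must be non-negative")
    if stress < 0.05:
        return StressCategory.CREDIBLE
    if stress < 0.10:
        return StressCategory.BASICALLY_CREDIBLE
    if stress < 0.20:
        return StressCategory.SOME_REFERENCE
    return StressCategory.UNTRUSTWORTHY


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation between two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateInputError("zero variance; correlation undefined")
    return float(pearsonr(x, y).statistic)


def curvature_environment_correlations(
    curvatures: pd.Series, env_table: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r (and p) of spectrum curvature against each environmental
    variable, aligned on site id.  Returns columns ``variable, r, p``."""
    common = curvatures.index.intersection(env_table.index)
    if len(common) < 3:
        raise ValueError("need >= 3 sites shared between curvatures and table")
    rows = []
    for col in env_table.columns:
        res = pearsonr(curvatures.loc[common], env_table.loc[common, col])
        rows.append({"variable": col, "r": float(res.statistic),
                     "p": float(res.pvalue)})
    return pd.DataFrame(rows, columns=["variable", "r", "p"])
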
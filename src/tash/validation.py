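"""Statistical toolkit for validating and applying the segmentation.

Covers the small set of analyses the method's outputs feed into:
Pearson correlation, partial correlation (residualising covariates),
the Meng–Rosenthal–Rubin z test comparing two dependent correlations
that share a variable (e.g. two automated methods each correlated with
the same manual reference), and the paired t test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError


@dataclass
class CorrelationComparison:
    """Result of comparing two dependent correlations with a common variable.

    r1, r2 are the correlations of methods 1 and 2 with the shared
    reference; r12 is the correlation between the two methods; z is
    positive when r1 > r2; p is one-tailed in the direction r1 > r2.
    """

    r1: float
    r2: float
    r12: float
    n: int
    z: float
    p_one_tailed: float


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-tailed t-distributed p value."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ParameterError("pearson needs two equal-length vectors of n ≥ 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ParameterError("pearson undefined for constant input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def partial_correlation(x, y, covariates) -> tuple[float, float]:
    """Correlation of x and y after removing *covariates* from both.

    Both variables are residualised against the covariate matrix (plus an
    intercept) by least squares; the p value is one-tailed (positive
    direction) from a t distribution with n − 2 − k degrees of freedom,
    where k is the number of covariates.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    z = np.asarray(covariates, dtype=np.float64)
    if z.size == 0:
        z = np.empty((x.size, 0))
    if z.ndim == 1:
        z = z[:, None]
    n = x.size
    if y.size != n or z.shape[0] != n:
        raise ParameterError("x, y and covariates must have matching length")
    k = z.shape[1]
    design = np.column_stack([np.ones(n), z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ParameterError("covariate matrix is rank deficient")
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ParameterError(
            "zero residual variance: a variable is collinear with covariates"
        )
    r = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    df = n - 2 - k
    if df < 1:
        raise ParameterError(f"not enough observations: df = {df}")
    t = r * np.sqrt(df / max(1e-300, 1 - r * r))
    p_one = float(sps.t.sf(t, df))
    return r, p_one


def dependent_correlation_z(r1: float, r2: float, r12: float,
                            n: int, dependent: bool = True) -> CorrelationComparison:
    """Compare two dependent correlations sharing one variable (Meng test).

    Uses Fisher's r-to-z transform with the Meng–Rosenthal–Rubin variance
    correction for the dependency through r12::

        z = (atanh r1 − atanh r2) · sqrt[(n − 3) / (2 (1 − r12) h)]
        h = (1 − f·r̄²) / (1 − r̄²),  r̄² = (r1² + r2²)/2
        f = min(1, (1 − r12) / (2 (1 − r̄²)))

    The one-tailed p is in the direction r1 > r2.  ``dependent=False``
    falls back to the naive independent-samples Fisher z (for comparison
    only; it is the wrong test when the correlations share a variable).
    """
    for name, r in (("r1", r1), ("r2", r2)):
        if not -1 < r < 1:
            raise ParameterError(f"{name} must lie strictly in (−1, 1)")
    if not -1 < r12 < 1:
        raise ParameterError("|r12| = 1: the two methods are degenerate copies")
    if n < 4:
        raise ParameterError("n must be ≥ 4")
    dz = np.arctanh(r1) - np.arctanh(r2)
    if dependent:
        rbar2 = (r1 * r1 + r2 * r2) / 2.0
        f = min(1.0, (1.0 - r12) / (2.0 * (1.0 - rbar2)))
        h = (1.0 - f * rbar2) / (1.0 - rbar2)
        z = dz * np.sqrt((n - 3) / (2.0 * (1.0 - r12) * h))
    else:
        z = dz / np.sqrt(2.0 / (n - 3))
    p_one = float(sps.norm.sf(z))
    return CorrelationComparison(r1=r1, r2=r2, r12=r12, n=n,
                                 z=float(z), p_one_tailed=p_one)


def paired_t(x, y) -> tuple[float, int, float]:
    """Paired t test on the differences x − y; df = n − 1."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ParameterError("paired_t needs two equal-length vectors, n ≥ 2")
    d = x - y
    if np.ptp(d) == 0:
        raise ParameterError("paired differences have zero variance")
    res = sps.ttest_rel(x, y)
    return float(res.statistic), int(x.size - 1), float(res.pvalue)


def method_comparison_table(df: pd.DataFrame,
                            reference: str = "manual",
                            method1: str = "tash",
                            method2: str = "freesurfer",
                            value: str = "volume",
                            group_cols: tuple[str, ...] = ("hemisphere",),
                            ) -> pd.DataFrame:
    """Per-group comparison of two methods' correlations with a reference.

    Expects a long table with one row per (subject, hemisphere, method)
    holding *value*; pivots it per group and reports r(method1, ref),
    r(method2, ref), the dependent-correlation z and its one-tailed p.
    """
    required = {"subject", "method", value, *group_cols}
    missing = required - set(df.columns)
    if missing:
        raise ParameterError(f"table is missing columns: {sorted(missing)}")
    rows = []
    for keys, sub in df.groupby(list(group_cols)):
        wide = sub.pivot_table(index="subject", columns="method",
                               values=value, aggfunc="first")
        wide = wide.dropna(subset=[reference, method1, method2])
        r1, _ = pearson(wide[method1], wide[reference])
        r2, _ = pearson(wide[method2], wide[reference])
        r12, _ = pearson(wide[method1], wide[method2])
        cmpres = dependent_correlation_z(r1, r2, r12, len(wide))
        key_dict = dict(zip(group_cols, keys if isinstance(keys, tuple) else (keys,)))
        rows.append({**key_dict, "n": len(wide),
                     f"r_{method1}": r1, f"r_{method2}": r2,
                     "r_between": r12, "z": cmpres.z,
                     "p_one_tailed": cmpres.p_one_tailed})
    return pd.DataFrame(rows)
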
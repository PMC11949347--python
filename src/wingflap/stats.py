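"""Descriptive statistics, outlier screening, normality testing and the
pairwise Spearman correlation table for the hen cohort.

The correlation engine is deliberately self-contained: the tie-corrected
Spearman rho is the product-moment correlation of mid-ranks, its two-sided
p-value comes from the t approximation on n-2 degrees of freedom, and for
very small samples (n <= 8) from exact enumeration of all n! rank
permutations.  No multiple-comparison correction is applied to the table;
the pairs are reported as-is.
"""
from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .heights import BoutResult
from .io import HenMorphometrics, morphometrics_frame

logger = logging.getLogger(__name__)

#: cohort variables, in the order the correlation table reports them
TABLE_VARIABLES = [
    "weight_kg", "folded_wing_cm", "extended_primary_cm",
    "extended_phalange_cm", "max_height_cm",
]
#: all 10 unordered pairs: morphometric pairs first, then height x each
TABLE_PAIRS: List[Tuple[str, str]] = [
    ("weight_kg", "folded_wing_cm"),
    ("weight_kg", "extended_primary_cm"),
    ("weight_kg", "extended_phalange_cm"),
    ("folded_wing_cm", "extended_primary_cm"),
    ("folded_wing_cm", "extended_phalange_cm"),
    ("extended_primary_cm", "extended_phalange_cm"),
    ("max_height_cm", "weight_kg"),
    ("max_height_cm", "folded_wing_cm"),
    ("max_height_cm", "extended_primary_cm"),
    ("max_height_cm", "extended_phalange_cm"),
]


@dataclass(frozen=True)
class SummaryStats:
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if not (self.min <= self.q1 <= self.median <= self.q3 <= self.max):
            raise ValueError("order statistics out of order")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class CorrelationResult:
    var_x: str
    var_y: str
    r: float            # NaN when undefined (a constant input)
    p: float
    n: int


def summarize(values: Sequence[float]) -> SummaryStats:
    """n, mean, SD (n-1 denominator), median, quartiles, extrema.

    Quartiles use linear interpolation of order statistics (the numpy
    default, type-7), the convention box-plot panels are drawn with here.
    Non-finite entries are ignored.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("summarize needs at least one finite value")
    sd = 0.0 if v.size == 1 else float(np.std(v, ddof=1))
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return SummaryStats(int(v.size), float(np.mean(v)), sd, float(med),
                        float(q1), float(q3), float(v.min()), float(v.max()))


def iqr_outliers(values: Sequence[float], k: float = 1.5) -> np.ndarray:
    """Tukey-fence outlier flags: outside ``[q1 - k*IQR, q3 + k*IQR]``.

    A constant vector (IQR = 0) flags nothing.  Non-finite entries are
    never flagged.
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if finite.sum() < 4:
        raise ValueError("outlier screening needs at least 4 values")
    q1, q3 = np.percentile(v[finite], [25, 75])
    iqr = q3 - q1
    flags = np.zeros(v.shape, dtype=bool)
    if iqr == 0:
        return flags
    flags[finite] = (v[finite] < q1 - k * iqr) | (v[finite] > q3 + k * iqr)
    return flags


def shapiro_wilk(values: Sequence[float]) -> Tuple[float, float]:
    """Shapiro-Wilk W and p, for the small samples this design produces."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 3:
        raise ValueError("Shapiro-Wilk needs n >= 3")
    w, p = sps.shapiro(v)
    return float(w), float(p)


def _midranks(v: np.ndarray) -> np.ndarray:
    return sps.rankdata(v, method="average")


def _rank_pearson(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    den = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if den == 0:
        return math.nan
    return float(rx @ ry) / den


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    labels: Tuple[str, str] = ("x", "y"),
    exact_n: int = 8,
) -> CorrelationResult:
    """Tie-corrected Spearman correlation with a two-sided p-value.

    Mid-ranks (average ranks on ties) feed a product-moment correlation.
    For n <= ``exact_n`` the p-value enumerates all n! permutations of one
    rank vector; otherwise it uses the t approximation with n-2 df.
    Missing values are handled pairwise-complete.  A constant input leaves
    rho undefined (NaN, with a warning).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 3:
        raise ValueError("Spearman correlation needs n >= 3 complete pairs")
    rx, ry = _midranks(x), _midranks(y)
    r = _rank_pearson(rx, ry)
    if math.isnan(r):
        warnings.warn(f"constant input in pair {labels}: correlation undefined")
        return CorrelationResult(labels[0], labels[1], math.nan, math.nan, n)

    if n <= exact_n:
        robs = abs(r) - 1e-12
        hits = total = 0
        for perm in itertools.permutations(ry):
            rp = _rank_pearson(rx, np.asarray(perm))
            total += 1
            if abs(rp) >= robs:
                hits += 1
        p = hits / total
    else:
        t = r * math.sqrt((n - 2) / max(1.0 - r * r, 1e-300))
        p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return CorrelationResult(labels[0], labels[1], r, min(p, 1.0), n)


def screen_outliers(
    df: pd.DataFrame,
    variables: Iterable[str] = TABLE_VARIABLES,
    k: float = 1.5,
) -> Tuple[pd.DataFrame, Dict[str, List[str]]]:
    """Per-variable Tukey screening; flagged values become NaN.

    Returns the screened frame and, per variable, the hen ids whose value
    was excluded.  Exclusions are logged, never silent.
    """
    out = df.copy()
    exclusions: Dict[str, List[str]] = {}
    for var in variables:
        if var not in out.columns:
            continue
        col = out[var].to_numpy(dtype=float)
        if np.isfinite(col).sum() < 4:
            continue
        flags = iqr_outliers(col, k=k)
        if flags.any():
            ids = [str(h) for h in out.loc[flags, "hen_id"]] if "hen_id" in out else \
                  [str(i) for i in np.flatnonzero(flags)]
            exclusions[var] = ids
            logger.info("outlier screening: excluding %s from %s", ids, var)
            out.loc[flags, var] = np.nan
    return out, exclusions


def cohort_frame(
    records: Sequence[HenMorphometrics],
    heights: Optional[Sequence[BoutResult]] = None,
) -> pd.DataFrame:
    """Join morphometrics with measured bout heights on hen id."""
    df = morphometrics_frame(records)
    if heights is not None:
        hdf = pd.DataFrame(
            [(b.hen_id, b.max_height_cm) for b in heights],
            columns=["hen_id", "max_height_cm"],
        )
        missing = sorted(set(df["hen_id"]) ^ set(hdf["hen_id"]))
        if missing:
            raise ValueError(f"hen ids do not join between tables: {missing}")
        df = df.drop(columns=["max_height_cm"]).merge(hdf, on="hen_id")
    return df


def correlation_table(
    records: Sequence[HenMorphometrics],
    heights: Optional[Sequence[BoutResult]] = None,
    exclude_outliers: bool = True,
    outlier_k: float = 1.5,
) -> List[CorrelationResult]:
    """All 10 unordered pairs among weight, the three wing measures and the
    maximum flap height, in fixed report order.

    Outlier-flagged values are excluded pairwise-complete (so a variable
    with one excluded value correlates on n-1 pairs).  No correction for
    multiple comparisons is applied.
    """
    df = cohort_frame(records, heights)
    if exclude_outliers:
        df, _ = screen_outliers(df, k=outlier_k)
    results = []
    for vx, vy in TABLE_PAIRS:
        x = df[vx].to_numpy(float)
        y = df[vy].to_numpy(float)
        n_complete = int((np.isfinite(x) & np.isfinite(y)).sum())
        if n_complete < 3:
            warnings.warn(f"pair ({vx}, {vy}): only {n_complete} complete "
                          "pairs; correlation undefined")
            results.append(CorrelationResult(vx, vy, math.nan, math.nan, n_complete))
            continue
        results.append(spearman(x, y, labels=(vx, vy)))
    return results


def correlation_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(f"{r.var_x} x {r.var_y}", r.r, r.p, r.n) for r in results],
        columns=["pair", "r", "p", "n"],
    )
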
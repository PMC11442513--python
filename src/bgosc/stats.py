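"""Group-level inference.

Monte Carlo permutation tests (sign flips for paired data, label exchange
otherwise), Benjamini-Hochberg FDR for independent comparison families,
cluster-based permutation correction across frequency bins for dependent
(spectrum-wise) comparisons, and Pearson correlation of hemisphere-averaged
per-subject estimates with symptom severity after a Lilliefors normality
screen. The clinical severity score is global per subject, so hemisphere
estimates are always averaged to one value per subject before correlating.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors as _lilliefors


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n_permutations: int = 0
    corrected: bool = False
    method: str = "permutation"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int
    normality_ok: bool
    lilliefors_p: tuple[float, float]
    method: str = "pearson"


def permutation_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    paired: bool = False,
    n_perm: int = 5000,
    seed: int | None = None,
) -> TestResult:
    """Two-sided Monte Carlo permutation test on the difference of means.

    Paired data: the null is built by randomly sign-flipping the paired
    differences. Unpaired: group labels are exchanged. The p-value uses the
    add-one rule, ``p = (1 + #{|null| >= |observed|}) / (1 + n_perm)``, so it
    can never be exactly zero.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired test requires equal-length samples")
        d = a - b
        stat = float(d.mean())
        if np.all(d == 0):
            warnings.warn("degenerate input: all paired differences are zero")
            return TestResult(0.0, 1.0, n_perm, method="permutation")
        signs = rng.choice([-1.0, 1.0], size=(n_perm, len(d)))
        null = (signs * d).mean(axis=1)
    else:
        stat = float(a.mean() - b.mean())
        pooled = np.concatenate([a, b])
        if np.all(pooled == pooled[0]):
            warnings.warn("degenerate input: all values identical")
            return TestResult(0.0, 1.0, n_perm, method="permutation")
        null = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(pooled)
            null[i] = perm[: len(a)].mean() - perm[len(a):].mean()
    p = (1.0 + np.sum(np.abs(null) >= abs(stat))) / (1.0 + n_perm)
    return TestResult(stat, float(p), n_perm, method="permutation")


def fdr_correct(p_values: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up. Returns (rejection mask, adjusted p).

    Adjusted values are the monotone BH q-values; empty input gives empty
    output.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    adj = ranked * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    adjusted = np.empty(n)
    adjusted[order] = adj
    # step-up rejection: largest k with p_(k) <= k/n * alpha, reject all below
    thresh = np.arange(1, n + 1) / n * alpha
    below = ranked <= thresh
    mask = np.zeros(n, dtype=bool)
    if below.any():
        k = np.max(np.nonzero(below)[0])
        mask[order[: k + 1]] = True
    return mask, adjusted


@dataclass
class Cluster:
    start: int
    stop: int  # exclusive bin index
    mass: float
    p_value: float


def cluster_permutation(
    spectra_a: np.ndarray,
    spectra_b: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    cluster_alpha: float = 0.05,
) -> list[Cluster]:
    """Paired cluster-based permutation test across frequency bins.

    Bin-wise paired t statistics are thresholded at the two-sided
    ``cluster_alpha`` critical t; contiguous supra-threshold bins of equal
    sign form clusters whose mass is the summed |t|. The null is the
    distribution of the maximum cluster mass under random sign flips of the
    unit-wise condition difference.
    """
    A = np.atleast_2d(np.asarray(spectra_a, dtype=float))
    B = np.atleast_2d(np.asarray(spectra_b, dtype=float))
    if A.shape != B.shape:
        raise ValueError("condition matrices must have matching shapes")
    n_units = A.shape[0]
    if n_units < 2:
        raise ValueError("cluster permutation needs at least two units")
    rng = np.random.default_rng(seed)
    d = A - B
    tcrit = sps.t.ppf(1.0 - cluster_alpha / 2.0, df=n_units - 1)

    def tstat(dd: np.ndarray) -> np.ndarray:
        sd = dd.std(axis=0, ddof=1)
        sd = np.where(sd == 0, np.inf, sd)
        return dd.mean(axis=0) / (sd / np.sqrt(n_units))

    def clusters_of(ts: np.ndarray) -> list[tuple[int, int, float]]:
        supra = np.abs(ts) > tcrit
        sign = np.sign(ts)
        out = []
        i = 0
        while i < len(ts):
            if supra[i]:
                j = i
                while j + 1 < len(ts) and supra[j + 1] and sign[j + 1] == sign[i]:
                    j += 1
                out.append((i, j + 1, float(np.abs(ts[i : j + 1]).sum())))
                i = j + 1
            else:
                i += 1
        return out

    observed = clusters_of(tstat(d))
    if not observed:
        return []
    null_max = np.zeros(n_perm)
    for k in range(n_perm):
        flips = rng.choice([-1.0, 1.0], size=(n_units, 1))
        cl = clusters_of(tstat(d * flips))
        null_max[k] = max((m for _, _, m in cl), default=0.0)
    result = []
    for start, stop, mass in observed:
        p = (1.0 + np.sum(null_max >= mass)) / (1.0 + n_perm)
        result.append(Cluster(start, stop, mass, float(p)))
    return result


def lilliefors_test(x: np.ndarray) -> tuple[float, float]:
    """Kolmogorov-Smirnov-Lilliefors test for normality: (statistic, p)."""
    stat, p = _lilliefors(np.asarray(x, dtype=float), dist="norm")
    return float(stat), float(p)


def correlate_with_severity(
    table: pd.DataFrame,
    column: str,
    severity_column: str = "severity",
    alpha: float = 0.05,
) -> CorrelationResult:
    """Pearson correlation of one per-subject estimate with severity.

    Both variables are first screened for normality (Lilliefors); a
    violation is flagged but the correlation is still reported. Requires at
    least three subjects, no missing values and non-zero variance.
    """
    for col in (column, severity_column):
        if col not in table.columns:
            raise KeyError(f"column {col!r} not in cohort table")
        if table[col].isna().any():
            raise ValueError(f"missing values in column {col!r}")
    x = table[column].to_numpy(dtype=float)
    y = table[severity_column].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("correlation requires at least three subjects")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    _, px = lilliefors_test(x)
    _, py = lilliefors_test(y)
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(
        r=float(r),
        p_value=float(p),
        n=len(x),
        normality_ok=bool(px > alpha and py > alpha),
        lilliefors_p=(px, py),
    )


def aggregate_hemispheres(
    per_hemisphere: pd.DataFrame,
    subject_column: str = "subject_id",
    severity: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Average hemisphere-level estimates to one row per subject.

    Numeric columns are arithmetic means across the subject's available
    hemispheres; subjects with no usable hemisphere for a column keep NaN
    there (and are dropped with a warning if every estimate is missing).
    When a severity table (subject_id, severity) is given it is joined on.
    """
    if subject_column not in per_hemisphere.columns:
        raise KeyError(f"missing {subject_column!r} column")
    numeric = per_hemisphere.select_dtypes(include=[np.number]).columns
    agg = per_hemisphere.groupby(subject_column, sort=True)[list(numeric)].mean().reset_index()
    all_nan = agg[list(numeric)].isna().all(axis=1)
    if all_nan.any():
        warnings.warn(f"dropping {int(all_nan.sum())} subject(s) with no usable hemisphere")
        agg = agg[~all_nan]
    if severity is not None:
        agg = agg.merge(severity[[subject_column, "severity"]], on=subject_column, how="inner")
    return agg
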
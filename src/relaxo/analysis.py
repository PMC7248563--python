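"""Regional statistics and agreement analytics.

Implements every comparison the study design calls for: per-region means
and SDs of a fitted map over a parcellation, Bland-Altman limits of
agreement (mean difference ± 2 sample SD), ordinary least-squares
regression against the identity line with a symmetric mean percent error,
nonparametric location tests (Mann–Whitney U, Wilcoxon signed-rank) with
exact small-sample enumeration, a Shapiro–Wilk normality gate, and the
scan–rescan two-standard-deviation criterion.

Conventions used throughout (stated because several are not forced by the
underlying formulas):

* all SDs are sample SDs (n−1 denominator); a single-voxel region gets SD 0;
* Bland-Altman limits use exactly ±2·SD, not ±1.96·SD;
* mean percent error is the symmetric form mean(|x−y| / ((x+y)/2)) × 100;
* Wilcoxon drops zero differences and mid-ranks ties;
* exact rank-test branches run for combined sample size ≤ 12, two-sided
  p = P(|T − center| ≥ |t − center|) under the permutation null;
* the normality gate is Shapiro–Wilk at α = 0.05 per sample; inter-center
  significance calls use α = 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import ParameterMap
from .volume_io import LabelVolume

__all__ = [
    "AgreementReport",
    "ScanRescanReport",
    "region_means",
    "bland_altman",
    "regression_to_identity",
    "mean_percent_error",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "shapiro_wilk",
    "scan_rescan_report",
    "compare_regions",
]

EXACT_MAX_N = 12
NORMALITY_ALPHA = 0.05
INTERCENTER_ALPHA = 0.01


# ---------------------------------------------------------------------------
# Regional statistics


def region_means(pm: ParameterMap, lv: LabelVolume) -> pd.DataFrame:
    """Mean/SD of valid voxels per region.

    Returns one row per LUT entry: ``label_id, region_name, n_valid_voxels,
    mean_ms, sd_ms, absent``. Regions with no valid voxel are flagged
    ``absent`` (mean/sd NaN), never dropped.
    """
    if pm.value_ms.shape != lv.labels.shape:
        raise ValueError(
            f"grid mismatch: map {pm.value_ms.shape} vs labels {lv.labels.shape}"
        )
    rows = []
    for r in lv.lut.itertuples():
        mask = (lv.labels == int(r.label_id)) & pm.valid
        vals = pm.value_ms[mask]
        n = int(vals.size)
        if n == 0:
            mean = sd = float("nan")
        elif n == 1:
            mean, sd = float(vals[0]), 0.0
        else:
            mean, sd = float(np.mean(vals)), float(np.std(vals, ddof=1))
        rows.append(
            {
                "label_id": int(r.label_id),
                "region_name": r.region_name,
                "n_valid_voxels": n,
                "mean_ms": mean,
                "sd_ms": sd,
                "absent": n == 0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Agreement analytics


def bland_altman(x, y) -> tuple[float, float, tuple[float, float]]:
    """Bland-Altman statistics of paired differences d = x − y.

    Returns ``(mean_diff, sd_diff, (lower, upper))`` with limits of
    agreement at mean ± 2 · sample SD.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return mean, sd, (mean - 2.0 * sd, mean + 2.0 * sd)


def mean_percent_error(x, y) -> float:
    """Symmetric mean percent error: mean(|x−y| / ((x+y)/2)) × 100."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    denom = (x + y) / 2.0
    if np.any(denom == 0):
        raise ValueError("undefined percent error: pair mean is zero")
    return float(np.mean(np.abs(x - y) / denom) * 100.0)


def regression_to_identity(x, y) -> tuple[float, float, float, float]:
    """OLS of y on x plus the symmetric mean percent error to identity.

    Returns ``(slope, intercept, r_squared, mean_percent_error)``.
    Requires n ≥ 3 and non-constant x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 pairs for regression")
    if np.ptp(x) == 0:
        raise ValueError("x is constant: slope undefined")
    res = stats.linregress(x, y)
    return (
        float(res.slope),
        float(res.intercept),
        float(res.rvalue**2),
        mean_percent_error(x, y),
    )


# ---------------------------------------------------------------------------
# Nonparametric tests


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def _two_sided_p(dist: np.ndarray, observed: float, center: float) -> float:
    """P(|T − center| ≥ |observed − center|) over an enumerated null."""
    dev = np.abs(dist - center)
    obs = abs(observed - center)
    return float(np.mean(dev >= obs - 1e-12))


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann–Whitney U test; returns (U of x, two-sided p).

    Exact enumeration of all group assignments (midrank ties handled) for
    combined n ≤ 12; tie-corrected normal approximation (scipy) otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be nonempty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    u_obs = float(np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2.0)
    if n1 + n2 <= EXACT_MAX_N:
        total = n1 + n2
        us = np.array(
            [
                sum(ranks[list(idx)]) - n1 * (n1 + 1) / 2.0
                for idx in combinations(range(total), n1)
            ]
        )
        p = _two_sided_p(us, u_obs, n1 * n2 / 2.0)
        return u_obs, p
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(d) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; ties mid-ranked. Returns
    ``(min(W+, W−), two-sided p)``. Exact sign-pattern enumeration for
    n ≤ 12 nonzero differences; normal approximation (scipy) otherwise.
    """
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero: no information")
    n = d.size
    ranks = _midranks(np.abs(d))
    w_plus = float(np.sum(ranks[d > 0]))
    w_minus = float(np.sum(ranks[d < 0]))
    w = min(w_plus, w_minus)
    if n <= EXACT_MAX_N:
        dist = np.array(
            [
                float(np.dot(signs, ranks))
                for signs in product((0.0, 1.0), repeat=n)
            ]
        )
        p = _two_sided_p(dist, w_plus, n * (n + 1) / 4.0)
        return w, p
    res = stats.wilcoxon(d, alternative="two-sided", method="approx")
    return float(res.statistic), float(res.pvalue)


def shapiro_wilk(x) -> float:
    """Shapiro–Wilk normality p-value (3 ≤ n ≤ 5000).

    Used only as the gate for choosing nonparametric tests. A constant
    sample raises (normality undefined for zero variance).
    """
    x = np.asarray(x, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError(f"Shapiro–Wilk requires 3 <= n <= 5000, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality test undefined")
    return float(stats.shapiro(x).pvalue)


# ---------------------------------------------------------------------------
# Composite reports


@dataclass
class AgreementReport:
    """Everything comparing two paired sets of regional values."""

    n_pairs: int
    bland_altman: tuple[float, float, tuple[float, float]]
    slope: float
    intercept: float
    r_squared: float
    mean_percent_error: float
    mann_whitney_p: float
    wilcoxon_p: float | None
    shapiro_p_x: float | None
    shapiro_p_y: float | None
    alpha: float = INTERCENTER_ALPHA

    @property
    def nonparametric_recommended(self) -> bool:
        ps = [p for p in (self.shapiro_p_x, self.shapiro_p_y) if p is not None]
        return any(p < NORMALITY_ALPHA for p in ps) if ps else True


def compare_regions(x, y) -> AgreementReport:
    """Full agreement report between two paired regional-value vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need >= 3 finite pairs")
    ba = bland_altman(x, y)
    slope, intercept, r2, mpe = regression_to_identity(x, y)
    _, mw_p = mann_whitney_u(x, y)
    d = x - y
    wil_p = None if np.all(d == 0) else wilcoxon_signed_rank(d)[1]

    def _safe_shapiro(v):
        try:
            return shapiro_wilk(v)
        except ValueError:
            return None

    return AgreementReport(
        n_pairs=int(x.size),
        bland_altman=ba,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        mean_percent_error=mpe,
        mann_whitney_p=mw_p,
        wilcoxon_p=wil_p,
        shapiro_p_x=_safe_shapiro(x),
        shapiro_p_y=_safe_shapiro(y),
    )


@dataclass
class ScanRescanReport:
    """Scan–rescan agreement: per-region table plus summary statistics."""

    table: pd.DataFrame  # label_id, region_name, diff_ms, within_2sd
    wilcoxon_p: float | None  # None when scans are identical
    slope: float
    intercept: float
    r_squared: float

    @property
    def all_within_2sd(self) -> bool:
        return bool(self.table["within_2sd"].all())


def scan_rescan_report(s1: pd.DataFrame, s2: pd.DataFrame) -> ScanRescanReport:
    """Compare regional statistics of two scans of the same subject.

    Per region: difference of means and the two-standard-deviation
    criterion ``|mean1 − mean2| < 2 · max(sd1, sd2)``; across regions:
    Wilcoxon signed-rank on the paired means (reported as "no difference",
    p = None, when all differences are zero) and regression to identity.
    """
    if not s1["label_id"].equals(s2["label_id"]):
        raise ValueError("region tables do not share a lut")
    merged = s1.merge(s2, on=["label_id", "region_name"], suffixes=("_1", "_2"))
    diff = merged["mean_ms_1"] - merged["mean_ms_2"]
    yardstick = 2.0 * np.maximum(merged["sd_ms_1"], merged["sd_ms_2"])
    table = pd.DataFrame(
        {
            "label_id": merged["label_id"],
            "region_name": merged["region_name"],
            "mean_1_ms": merged["mean_ms_1"],
            "mean_2_ms": merged["mean_ms_2"],
            "diff_ms": diff,
            # a zero difference always satisfies the criterion, even for a
            # uniform region whose SD yardstick is itself zero
            "within_2sd": (np.abs(diff) < yardstick) | (diff == 0),
        }
    )
    finite = np.isfinite(merged["mean_ms_1"]) & np.isfinite(merged["mean_ms_2"])
    x = merged.loc[finite, "mean_ms_1"].to_numpy()
    y = merged.loc[finite, "mean_ms_2"].to_numpy()
    d = x - y
    wil_p = None if np.all(d == 0) else wilcoxon_signed_rank(d)[1]
    slope, intercept, r2, _ = regression_to_identity(x, y)
    return ScanRescanReport(
        table=table, wilcoxon_p=wil_p, slope=slope, intercept=intercept, r_squared=r2
    )
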
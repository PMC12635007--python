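"""Association and paired-intervention statistics.

Pearson/Spearman correlation with Benjamini-Hochberg FDR across a family of
pairs, Mann-Whitney U group comparisons, and the paired pre/post analysis:
per-subject change ``dP_i = post_i - pre_i``, its median and IQR, a
Wilcoxon matched-pairs signed-rank test, and the standardized effect size

    |r| = |Z| / sqrt(n)

where Z is the tie- and continuity-corrected normal standardization of the
signed-rank statistic and n the number of pairs contributing (zero
differences are dropped before ranking, Wilcoxon's original treatment).
Effect magnitudes: |r| >= 0.5 large, >= 0.3 medium, >= 0.1 small, else
negligible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationResult",
    "PairedOutcome",
    "correlate",
    "correlation_matrix",
    "mann_whitney",
    "wilcoxon_z",
    "intervention_analysis",
    "effect_size_r",
    "effect_magnitude",
]

EXACT_MW_LIMIT = 20  # exact Mann-Whitney for groups up to this size, no ties


@dataclass
class CorrelationResult:
    var1: str
    var2: str
    method: str
    r: float
    p: float
    fdr: float = math.nan
    significant: bool = False


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Correlation coefficient and two-sided P for one variable pair.

    Pairwise-complete observations; Spearman uses average ranks for ties.
    Raises on zero variance (the coefficient is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def correlation_matrix(table: pd.DataFrame, method: str = "spearman",
                       x_vars: list[str] | None = None,
                       y_vars: list[str] | None = None,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Correlate variable pairs and adjust P-values by Benjamini-Hochberg.

    With ``x_vars``/``y_vars`` the tested family is their cross product
    (e.g. clock readouts vs HRV panel); otherwise all distinct column pairs.
    All pairs of one invocation form a single FDR family.
    """
    if x_vars is None or y_vars is None:
        pairs = list(combinations(table.columns, 2))
    else:
        pairs = [(a, b) for a in x_vars for b in y_vars if a != b]
    if not pairs:
        raise ValueError("no variable pairs to test")
    rows = []
    for a, b in pairs:
        try:
            r, p = correlate(table[a], table[b], method)
            err = ""
        except ValueError as exc:
            r, p, err = math.nan, math.nan, str(exc)
        rows.append({"var1": a, "var2": b, "method": method, "r": r, "p": p,
                     "error": err})
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["fdr"] = np.nan
    if ok.any():
        out.loc[ok, "fdr"] = multipletests(out.loc[ok, "p"],
                                           method="fdr_bh")[1]
    out["significant"] = out["fdr"] <= alpha
    return out


def mann_whitney(a, b, exact_limit: int = EXACT_MW_LIMIT
                 ) -> tuple[float, float]:
    """Mann-Whitney U (for group ``a``) with two-sided P.

    Exact null distribution when both groups are small (<= ``exact_limit``)
    and tie-free; otherwise the tie-corrected normal approximation with
    continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = ("exact" if len(a) <= exact_limit and len(b) <= exact_limit
              and not ties else "asymptotic")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_z(delta: np.ndarray) -> tuple[float, int]:
    """Tie/continuity-corrected Z of the signed-rank statistic.

    Zero differences are dropped; returns (Z, n) with n the pairs that were
    ranked.  Z is signed (positive when values increased); Eq.-style effect
    sizes use |Z|.  Always computed from the normal standardization so the
    effect size is defined even when the P-value itself is exact.
    """
    d = np.asarray(delta, dtype=float)
    d = d[d != 0]
    m = len(d)
    if m == 0:
        return math.nan, 0
    ranks = sps.rankdata(np.abs(d))
    t_plus = float(ranks[d > 0].sum())
    mu = m * (m + 1) / 4.0
    # tie correction over groups of tied absolute values
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts ** 3 - counts) / 48.0).sum())
    var = m * (m + 1) * (2 * m + 1) / 24.0 - tie_term
    if var <= 0:
        return math.nan, m
    cc = 0.5 * np.sign(t_plus - mu) if t_plus != mu else 0.0
    return float((t_plus - mu - cc) / math.sqrt(var)), m


def effect_size_r(z: float, n: int) -> float:
    """Standardized effect size |r| = |Z| / sqrt(n) for a signed-rank Z."""
    if n <= 0 or math.isnan(z):
        return math.nan
    return abs(z) / math.sqrt(n)


def effect_magnitude(r_abs: float) -> str:
    if math.isnan(r_abs):
        return "undefined"
    if r_abs >= 0.5:
        return "large"
    if r_abs >= 0.3:
        return "medium"
    if r_abs >= 0.1:
        return "small"
    return "negligible"


@dataclass
class PairedOutcome:
    """Paired pre/post summary for one variable."""

    variable: str
    delta: np.ndarray       # dP_i = post - pre per subject
    median: float
    iqr: float
    z: float
    p: float
    effect_r: float         # |Z|/sqrt(n)
    n: int                  # pairs contributing (zeros dropped)
    magnitude: str


def intervention_analysis(pre, post, variable: str = "") -> PairedOutcome:
    """Paired analysis of an intervention variable.

    Positive median change means the variable increased after the
    intervention.  When every pair is unchanged the test is undefined and
    the effect size is reported as 0.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if len(pre) != len(post):
        raise ValueError("pre and post must have equal length")
    if len(pre) < 5:
        raise ValueError("need at least 5 pairs")
    delta = post - pre
    q75, q25 = np.percentile(delta, [75, 25])
    z, n = wilcoxon_z(delta)
    if n == 0:
        return PairedOutcome(variable=variable, delta=delta,
                             median=float(np.median(delta)),
                             iqr=float(q75 - q25), z=math.nan, p=math.nan,
                             effect_r=0.0, n=0, magnitude="negligible")
    nz = delta[delta != 0]
    method = "exact" if (n <= 25 and len(np.unique(np.abs(nz))) == len(nz)
                         ) else "approx"
    p = float(sps.wilcoxon(nz, alternative="two-sided", method=method,
                           correction=True).pvalue)
    r_abs = effect_size_r(z, n)
    return PairedOutcome(variable=variable, delta=delta,
                         median=float(np.median(delta)), iqr=float(q75 - q25),
                         z=z, p=p, effect_r=r_abs, n=n,
                         magnitude=effect_magnitude(r_abs))
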
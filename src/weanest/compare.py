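"""Agreement statistics for weaning estimates from multiple methods.

Given a wide table (one row per individual, one column per method, entries in
years) the suite computes the Friedman test (non-parametric repeated-measures
ANOVA over within-individual ranks, with tie correction), pairwise Lin's
concordance correlation coefficients (population moments), pairwise Pearson
correlations, Bland-Altman bias and +/-1.96 SD limits of agreement, and a
per-individual absolute-difference table.  The module consumes estimates as
plain columns; it never runs the external estimators itself.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps


def friedman_test(matrix: np.ndarray | pd.DataFrame) -> tuple[float, float]:
    """Friedman chi-square and asymptotic p for an individuals x methods matrix.

    Within-row ranks (ties share the mean rank) feed the standard statistic
    with tie correction; p comes from the chi-square distribution with k-1
    degrees of freedom.  ``k = 2`` raises (use a sign test instead).  A matrix
    whose rows are all completely tied returns (0.0, 1.0).
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("matrix must be 2-D (individuals x methods)")
    n, k = x.shape
    if k == 2:
        raise ValueError("Friedman test needs >= 3 methods; for 2 use a sign test")
    if k < 3 or n < 3:
        raise ValueError("need >= 3 methods and >= 3 individuals")
    ranks = np.apply_along_axis(sps.rankdata, 1, x)
    rank_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(rank_sums**2) - 3.0 * n * (k + 1)
    # Tie correction: 1 - sum(t^3 - t)/(n k (k^2 - 1)) over tie groups per row.
    tie_term = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    denom = 1.0 - tie_term / (n * k * (k**2 - 1))
    if denom <= 0.0:
        return 0.0, 1.0  # every row fully tied
    chi2 = float(chi2 / denom)
    p = float(sps.chi2.sf(chi2, df=k - 1))
    return chi2, p


def ccc(x, y, bias_corrected: bool = False) -> float:
    """Lin's concordance correlation coefficient.

    ``2*s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2)`` with population (1/n)
    moments by default; ``bias_corrected=True`` switches to n-1 moments for
    cross-checking other software.  Returns NaN when both vectors are constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-D vectors of length >= 3")
    ddof = 1 if bias_corrected else 0
    sx2 = x.var(ddof=ddof)
    sy2 = y.var(ddof=ddof)
    mx, my = x.mean(), y.mean()
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0.0:
        return float("nan")
    n = x.size
    sxy = float(np.dot(x - mx, y - my)) / (n - ddof)
    return float(2.0 * sxy / denom)


def pearson_r(x, y) -> float:
    """Product-moment correlation; NaN when either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-D vectors of length >= 3")
    if x.var() == 0.0 or y.var() == 0.0:
        return float("nan")
    return float(sps.pearsonr(x, y).statistic)


def bland_altman(x, y) -> tuple[float, float, float, pd.DataFrame]:
    """Bias and limits of agreement for method x vs method y.

    Differences ``d = x - y``; bias is their mean and the limits are
    ``bias +/- 1.96 * sd(d)`` with the sample (n-1) standard deviation.  Also
    returns the ((x+y)/2, d) table used for plotting.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-D vectors")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    table = pd.DataFrame({"mean": (x + y) / 2.0, "diff": d})
    return bias, bias - 1.96 * sd, bias + 1.96 * sd, table


@dataclass
class ComparisonReport:
    friedman_chi2: float
    friedman_p: float
    ccc_matrix: pd.DataFrame
    pearson_matrix: pd.DataFrame
    bland_altman: dict[tuple[str, str], dict]
    abs_diff: pd.DataFrame  # per-individual |method_i - method_j|

    def to_json(self, path: str | Path | None = None) -> dict:
        d = {
            "friedman": {"chi2": self.friedman_chi2, "p": self.friedman_p},
            "ccc": self.ccc_matrix.to_dict(),
            "pearson": self.pearson_matrix.to_dict(),
            "bland_altman": {
                f"{a}__vs__{b}": {k: v for k, v in rec.items() if k != "table"}
                for (a, b), rec in self.bland_altman.items()
            },
        }
        if path is not None:
            Path(path).write_text(json.dumps(d, indent=2))
        return d


def compare_methods(estimates: pd.DataFrame) -> ComparisonReport:
    """Full agreement suite over a wide estimates table (>= 3 methods, >= 3 rows).

    The index (or a ``sample_id`` column) identifies individuals; every other
    column is a method.  Missing entries are not allowed for the tested subset.
    """
    df = estimates.copy()
    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
    methods = list(df.columns)
    if len(methods) < 2 or len(df) < 3:
        raise ValueError("need >= 2 methods and >= 3 individuals")
    if df.isna().any().any():
        raise ValueError("missing entries in the estimate matrix")

    if len(methods) >= 3:
        chi2, p = friedman_test(df.to_numpy())
    else:
        chi2, p = float("nan"), float("nan")

    ccc_m = pd.DataFrame(np.eye(len(methods)), index=methods, columns=methods)
    r_m = pd.DataFrame(np.eye(len(methods)), index=methods, columns=methods)
    ba: dict[tuple[str, str], dict] = {}
    rows = []
    for a, b in itertools.combinations(methods, 2):
        xa, xb = df[a].to_numpy(), df[b].to_numpy()
        c = ccc(xa, xb)
        r = pearson_r(xa, xb)
        ccc_m.loc[a, b] = ccc_m.loc[b, a] = c
        r_m.loc[a, b] = r_m.loc[b, a] = r
        bias, lo, hi, table = bland_altman(xa, xb)
        ba[(a, b)] = {"bias": bias, "loa_lo": lo, "loa_hi": hi, "table": table}
        for sid, va, vb in zip(df.index, xa, xb):
            rows.append({"sample_id": sid, "pair": f"{a}__vs__{b}",
                         "abs_diff": abs(va - vb)})
    return ComparisonReport(
        friedman_chi2=chi2,
        friedman_p=p,
        ccc_matrix=ccc_m,
        pearson_matrix=r_m,
        bland_altman=ba,
        abs_diff=pd.DataFrame(rows),
    )
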
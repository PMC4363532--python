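"""Disease-associated coexpression threshold via the two-sample KS statistic.

For each candidate threshold t the *inverted* empirical CDFs (survival
fractions) F_d(t) = Prob(C_d >= t) and F_n(t) = Prob(C_n >= t) give the
fraction of gene pairs at or above t in each group; the inequality is
inverted relative to the usual CDF because interest lies in strong
coexpression. The optimal threshold C* maximizes the absolute deviation
D = max_t |F_d(t) - F_n(t)| — the two-sample Kolmogorov-Smirnov statistic on
the coexpression distributions. At C* the pairs dichotomize into strong
(C >= C*) and weak classes, whose association with the group is verified by
an uncorrected Pearson chi-square on the 2x2 contingency table.

Note the KS p-value treats the per-group coexpression levels as two
independent samples; in reality the G*(G-1)/2 pair statistics of a G-gene
panel are dependent, so the p-value is a descriptive index rather than an
exact error rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats

from .coexpression import CoexpressionTable


@dataclass
class SurvivalCurve:
    """Per-threshold strong-pair fractions for the two groups.

    ``thresholds`` is an ordered grid in [0, 1]; ``f_disease[k]`` and
    ``f_normal[k]`` are the fractions of pairs with coexpression level at or
    above ``thresholds[k]`` in each group. Both fractions are non-increasing
    step functions equal to 1 at t = 0.
    """

    thresholds: np.ndarray
    f_disease: np.ndarray
    f_normal: np.ndarray
    n_pairs: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "f_disease": self.f_disease,
                "f_normal": self.f_normal,
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def survival_fraction(values: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Fraction of ``values`` at or above each threshold (inclusive >=)."""
    values = np.sort(np.asarray(values, dtype=float))
    # count of values >= t  ==  n - searchsorted_left(t)
    idx = np.searchsorted(values, np.asarray(thresholds, dtype=float), side="left")
    return (values.size - idx) / values.size


def survival_curves(
    table: CoexpressionTable,
    grid: str | float = "observed",
) -> SurvivalCurve:
    """Evaluate the inverted CDFs of C_d and C_n on a threshold grid.

    ``grid="observed"`` uses the sorted union of all observed coexpression
    levels plus {0, 1}; this grid is exact because the step functions only
    change at observed values. A float ``grid`` is a uniform step (e.g.
    0.0001 evaluates every candidate threshold from 0 to 1 at that spacing).
    """
    df = table.defined()
    if df.empty:
        raise ValueError("coexpression table has no defined pairs")
    c_d = df["c_disease"].to_numpy()
    c_n = df["c_normal"].to_numpy()
    if isinstance(grid, str):
        if grid != "observed":
            raise ValueError(f"unknown grid {grid!r}")
        ts = np.unique(np.concatenate([[0.0, 1.0], c_d, c_n]))
    else:
        step = float(grid)
        if not 0 < step <= 0.5:
            raise ValueError("uniform grid step must be in (0, 0.5]")
        ts = np.round(np.arange(0.0, 1.0 + step / 2, step), 12)
    return SurvivalCurve(
        thresholds=ts,
        f_disease=survival_fraction(c_d, ts),
        f_normal=survival_fraction(c_n, ts),
        n_pairs=len(df),
    )


def optimal_threshold(curve: SurvivalCurve) -> tuple[float, float]:
    """Threshold maximizing |F_d - F_n| and the deviation D achieved.

    Ties in D are broken toward the smallest threshold (the most inclusive
    strong class).
    """
    # compare integer pair counts so exact ties are not broken by float
    # round-off (the fractions are multiples of 1/n_pairs)
    n = curve.n_pairs
    dev_counts = np.rint(np.abs(curve.f_disease - curve.f_normal) * n).astype(int)
    k = int(np.argmax(dev_counts))  # first (smallest t) maximum
    return float(curve.thresholds[k]), float(
        abs(curve.f_disease[k] - curve.f_normal[k])
    )


def ks_pvalue(d: float, n_disease: int, n_normal: int) -> float:
    """Asymptotic two-sample Kolmogorov p-value for deviation ``d``.

    p = Q(sqrt(n*m/(n+m)) * D) with Q the Kolmogorov tail function
    2 * sum_{k>=1} (-1)^(k-1) exp(-2 k^2 lambda^2).
    """
    if not 0.0 <= d <= 1.0:
        raise ValueError("D must lie in [0, 1]")
    if n_disease < 1 or n_normal < 1:
        raise ValueError("sample sizes must be >= 1")
    lam = np.sqrt(n_disease * n_normal / (n_disease + n_normal)) * d
    return float(special.kolmogorov(lam))


def dichotomize(table: CoexpressionTable, c_star: float) -> pd.DataFrame:
    """2x2 contingency counts {strong, weak} x {disease, normal}.

    A pair is strong when its coexpression level is at or above the
    threshold (inclusive >=, consistent with the survival curves).
    """
    df = table.defined()
    strong_d = int((df["c_disease"] >= c_star).sum())
    strong_n = int((df["c_normal"] >= c_star).sum())
    n = len(df)
    return pd.DataFrame(
        [[strong_d, strong_n], [n - strong_d, n - strong_n]],
        index=pd.Index(["strong", "weak"], name="coexpression"),
        columns=pd.Index(["disease", "normal"], name="group"),
    )


def chi_square(table: pd.DataFrame | np.ndarray) -> tuple[float, float]:
    """Pearson chi-square (1 d.f., no continuity correction) on a 2x2 table."""
    counts = np.asarray(table, dtype=float)
    if counts.shape != (2, 2):
        raise ValueError("expected a 2x2 contingency table")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: zero marginal total")
    res = stats.chi2_contingency(counts, correction=False)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ThresholdResult:
    """Optimal threshold with its KS and chi-square verification statistics."""

    c_star: float
    d: float
    ks_p: float
    table: pd.DataFrame  # 2x2 {strong, weak} x {disease, normal}
    chi2: float
    chi2_p: float
    curve: SurvivalCurve

    def report(self) -> str:
        t = self.table
        lines = [
            "Differential coexpression threshold",
            "-----------------------------------",
            f"optimal threshold C*      : {self.c_star:.4f}",
            f"KS deviation D            : {self.d:.4f}",
            f"KS p-value (asymptotic)   : {self.ks_p:.4g}",
            "contingency (strong/weak x disease/normal):",
            f"  strong  {int(t.loc['strong', 'disease']):>5d} {int(t.loc['strong', 'normal']):>5d}",
            f"  weak    {int(t.loc['weak', 'disease']):>5d} {int(t.loc['weak', 'normal']):>5d}",
            f"chi-square (1 d.f., uncorrected): {self.chi2:.4f}",
            f"chi-square p-value        : {self.chi2_p:.4g}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "c_star": self.c_star,
            "d": self.d,
            "ks_p": self.ks_p,
            "strong_disease": int(self.table.loc["strong", "disease"]),
            "strong_normal": int(self.table.loc["strong", "normal"]),
            "weak_disease": int(self.table.loc["weak", "disease"]),
            "weak_normal": int(self.table.loc["weak", "normal"]),
            "chi2": self.chi2,
            "chi2_p": self.chi2_p,
        }


def find_threshold(
    table: CoexpressionTable,
    grid: str | float = "observed",
) -> ThresholdResult:
    """Full threshold-selection stage: curves, C*, D, KS p, chi-square."""
    curve = survival_curves(table, grid=grid)
    c_star, d = optimal_threshold(curve)
    p = ks_pvalue(d, curve.n_pairs, curve.n_pairs)
    cont = dichotomize(table, c_star)
    chi2, chi2_p = chi_square(cont)
    return ThresholdResult(
        c_star=c_star, d=d, ks_p=p, table=cont, chi2=chi2, chi2_p=chi2_p, curve=curve
    )
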
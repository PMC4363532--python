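"""Per-group coexpression of all unordered gene pairs.

The coexpression level of a gene pair is the absolute value of the Pearson
correlation between the two genes' expression profiles across one group's
samples: C = |cor(x_i, x_j)|, a scalar in [0, 1]. Taking the absolute value
deliberately erases the correlation sign, so that strong inhibitory
(negative) relationships score as highly as activating ones. The level is
computed independently for the disease and the normal group, over each
group's samples only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import DISEASE, NORMAL, ExpressionDataset

logger = logging.getLogger(__name__)

#: Column order of the pair table.
PAIR_COLUMNS = ("gene_a", "gene_b", "r_disease", "r_normal", "c_disease", "c_normal")


class ZeroVarianceError(ValueError):
    """Pearson correlation is undefined for a constant profile."""


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation of two equal-length profiles.

    Raises :class:`ZeroVarianceError` when either profile is constant, rather
    than silently returning 0 or NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("profiles must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 samples for a sample correlation")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        raise ZeroVarianceError("correlation undefined: constant profile")
    r = float((xc @ yc) / (sx * sy))
    return float(np.clip(r, -1.0, 1.0))


@dataclass
class CoexpressionTable:
    """All unordered gene pairs with per-group correlation and coexpression.

    ``pairs`` has one row per unordered pair in canonical (lexicographic)
    order with columns ``gene_a, gene_b, r_disease, r_normal, c_disease,
    c_normal``. Pairs whose correlation is undefined in either group (a
    constant gene profile) carry NaN and are excluded from the statistics via
    :meth:`defined`; the exclusion count is logged at build time.
    """

    pairs: pd.DataFrame
    n_genes: int

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_excluded(self) -> int:
        return int((~self._defined_mask()).sum())

    def _defined_mask(self) -> pd.Series:
        return self.pairs[["c_disease", "c_normal"]].notna().all(axis=1)

    def defined(self) -> pd.DataFrame:
        """Rows with a defined coexpression level in both groups."""
        return self.pairs[self._defined_mask()]

    def write(self, path: str | Path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def read(cls, path: str | Path) -> "CoexpressionTable":
        df = pd.read_csv(path, sep="\t")
        n_pairs = len(df)
        # invert G*(G-1)/2
        n_genes = int(round((1 + np.sqrt(1 + 8 * n_pairs)) / 2))
        return cls(df[list(PAIR_COLUMNS)], n_genes=n_genes)


def _group_correlations(values: pd.DataFrame) -> np.ndarray:
    """Gene-by-gene correlation matrix; NaN rows/cols for constant genes."""
    arr = values.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(arr)
    R = np.clip(R, -1.0, 1.0)
    R[sd == 0.0, :] = np.nan
    R[:, sd == 0.0] = np.nan
    return R


def coexpression_table(dataset: ExpressionDataset) -> CoexpressionTable:
    """Compute signed correlation and coexpression level for every pair.

    Returns one row per unordered gene pair (G*(G-1)/2 rows for G genes);
    a 20-gene panel yields 190 pairs. Correlations are computed within each
    group's samples separately, never pooled.
    """
    if dataset.n_genes < 2:
        raise ValueError("need at least 2 genes to form pairs")
    genes = dataset.gene_symbols
    R_d = _group_correlations(dataset.group_values(DISEASE))
    R_n = _group_correlations(dataset.group_values(NORMAL))
    iu, ju = np.triu_indices(len(genes), k=1)
    rows = []
    for i, j in zip(iu, ju):
        a, b = sorted((genes[i], genes[j]))
        rows.append((a, b, R_d[i, j], R_n[i, j]))
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "r_disease", "r_normal"])
    df["c_disease"] = df["r_disease"].abs()
    df["c_normal"] = df["r_normal"].abs()
    table = CoexpressionTable(df[list(PAIR_COLUMNS)], n_genes=len(genes))
    if table.n_excluded:
        logger.warning(
            "%d gene pairs have an undefined correlation (constant profile) "
            "and are excluded from threshold statistics", table.n_excluded,
        )
    return table
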
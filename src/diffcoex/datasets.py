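"""Expression-matrix containers and I/O.

The pipeline's raw input is a gene-by-sample expression matrix (tab-delimited,
first column gene/probe symbol, header row of sample ids) together with a
two-column sample-to-group file assigning every sample to the ``disease`` or
``normal`` group. Values are assumed already normalized (typically log scale);
no transformation is applied on read unless requested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DISEASE = "disease"
NORMAL = "normal"
GROUPS = (DISEASE, NORMAL)

#: The 20-gene apoptosis/autophagy panel used throughout the worked examples:
#: BCL2-family apoptosis regulators, E2F cell-cycle transcription factors,
#: PI3K/AKT subunits and core autophagy genes.
APOPTOSIS_AUTOPHAGY_PANEL: tuple[str, ...] = (
    "MCL1", "BCL2", "BAD", "BAX", "BAK1",
    "E2F1", "E2F2", "E2F3", "MYC",
    "PIK3R2", "PIK3R3", "PIK3R5", "AKT1", "AKT2", "AKT3",
    "ATG5", "ATG7", "ATG12", "MAP1LC3B", "BECN1",
)


class ExpressionIOError(ValueError):
    """Raised for malformed expression matrices or group files."""


@dataclass
class ExpressionDataset:
    """A validated gene-by-sample expression matrix with two-group labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes in rows (index = gene symbols), samples in columns.
    group_of : mapping of sample id -> ``"disease"`` | ``"normal"``.
    """

    values: pd.DataFrame
    group_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values)
        self.group_of = dict(self.group_of)
        self._validate()

    def _validate(self) -> None:
        idx = self.values.index
        if idx.duplicated().any():
            dups = sorted(set(idx[idx.duplicated()]))
            raise ExpressionIOError(f"duplicate gene symbols: {dups}")
        cols = self.values.columns
        if cols.duplicated().any():
            dups = sorted(set(cols[cols.duplicated()]))
            raise ExpressionIOError(f"duplicate sample ids: {dups}")
        missing = [s for s in cols if s not in self.group_of]
        if missing:
            raise ExpressionIOError(f"samples missing from group file: {missing}")
        bad = {s: g for s, g in self.group_of.items() if g not in GROUPS}
        if bad:
            raise ExpressionIOError(
                f"group labels must be one of {GROUPS}, got {bad}"
            )
        for group in GROUPS:
            n = len(self.samples_in(group))
            if n < 3:
                raise ExpressionIOError(
                    f"group {group!r} has {n} samples; at least 3 are required "
                    "for a non-degenerate Pearson correlation"
                )
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ExpressionIOError("expression matrix contains non-numeric cells")

    # -- basic accessors ---------------------------------------------------
    @property
    def gene_symbols(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.group_of.get(s) == group]

    def group_values(self, group: str) -> pd.DataFrame:
        """Expression sub-matrix restricted to one group's samples."""
        return self.values[self.samples_in(group)]

    # -- I/O ---------------------------------------------------------------
    def write(self, matrix_path: str | Path, groups_path: str | Path) -> None:
        """Write the tab-delimited matrix and the two-column group file."""
        out = self.values.copy()
        out.index.name = "gene"
        out.to_csv(matrix_path, sep="\t")
        with open(groups_path, "w") as fh:
            for s in self.sample_ids:
                fh.write(f"{s}\t{self.group_of[s]}\n")


@dataclass(frozen=True)
class GenePanel:
    """An ordered list of unique HUGO symbols selected for analysis."""

    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.symbols) < 2:
            raise ValueError("a gene panel needs at least 2 symbols")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("panel symbols must be unique")

    @classmethod
    def from_iterable(cls, symbols: Iterable[str]) -> "GenePanel":
        return cls(tuple(symbols))

    @classmethod
    def from_file(cls, path: str | Path) -> "GenePanel":
        """One symbol per line; blank lines and '#' comments ignored."""
        syms = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                syms.append(line.split("\t")[0])
        return cls(tuple(syms))

    def __len__(self) -> int:
        return len(self.symbols)


def default_panel() -> GenePanel:
    """The 20-gene apoptosis/autophagy panel."""
    return GenePanel(APOPTOSIS_AUTOPHAGY_PANEL)


def read_expression(
    matrix_path: str | Path,
    groups_path: str | Path,
    *,
    log2: bool = False,
) -> ExpressionDataset:
    """Read a tab-delimited expression matrix and its sample-group file.

    The matrix has a header row of sample ids and the gene/probe symbol in the
    first column; GEO "series matrix" style comment lines starting with ``!``
    are skipped. ``log2`` applies log2(x + 1) for raw-scale inputs.
    """
    df = pd.read_csv(matrix_path, sep="\t", index_col=0, comment="!")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        bad = _first_non_numeric(df)
        raise ExpressionIOError(
            f"non-numeric expression value at gene {bad[0]!r}, sample {bad[1]!r}"
        ) from exc
    if log2:
        df = np.log2(df + 1.0)
    group_of = read_groups(groups_path)
    return ExpressionDataset(df, group_of)


def read_groups(path: str | Path) -> dict[str, str]:
    """Read a two-column tab-delimited sample -> group file."""
    group_of: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ExpressionIOError(f"{path}:{ln}: expected 2 tab-separated fields")
        sample, group = parts
        if sample in group_of:
            raise ExpressionIOError(f"{path}:{ln}: duplicate sample id {sample!r}")
        group_of[sample] = group
    return group_of


def _first_non_numeric(df: pd.DataFrame) -> tuple[str, str]:
    for gene, row in df.iterrows():
        for sample, v in row.items():
            try:
                float(v)
            except (TypeError, ValueError):
                return str(gene), str(sample)
    return "?", "?"


@dataclass
class PanelSelection:
    """Outcome of selecting a gene panel from a dataset."""

    dataset: ExpressionDataset
    found: list[str]
    missing: list[str]
    collapsed: dict[str, int]  # symbol -> number of probe rows collapsed


def select_panel(
    dataset: ExpressionDataset,
    panel: GenePanel,
    *,
    symbol_of: Mapping[str, str] | None = None,
    collapse: Literal["max_mean", "mean"] = "max_mean",
) -> PanelSelection:
    """Restrict a dataset to a gene panel, collapsing probes to genes.

    ``symbol_of`` maps probe row ids to gene symbols when the matrix is at
    probe level; by default row ids are taken as symbols. Rows mapping to the
    same symbol are collapsed: ``max_mean`` keeps the row with the highest
    mean expression, ``mean`` averages the rows per sample. Panel symbols not
    found are reported in the result, never silently dropped.
    """
    if collapse not in ("max_mean", "mean"):
        raise ValueError(f"unknown collapse rule {collapse!r}")
    sym = dict(symbol_of) if symbol_of else {g: g for g in dataset.gene_symbols}
    rows_of: dict[str, list[str]] = {}
    for row_id in dataset.gene_symbols:
        s = sym.get(row_id)
        if s in panel.symbols:
            rows_of.setdefault(s, []).append(row_id)

    found = [s for s in panel.symbols if s in rows_of]
    missing = [s for s in panel.symbols if s not in rows_of]
    if len(found) < 2:
        raise ExpressionIOError(
            f"only {len(found)} panel symbols present in the dataset; need >= 2"
        )
    if missing:
        logger.warning("panel symbols absent from dataset: %s", missing)

    collapsed: dict[str, int] = {}
    out_rows = {}
    for s in found:
        rows = rows_of[s]
        sub = dataset.values.loc[rows]
        if len(rows) == 1:
            out_rows[s] = sub.iloc[0]
        elif collapse == "mean":
            out_rows[s] = sub.mean(axis=0)
            collapsed[s] = len(rows)
        else:  # max_mean
            out_rows[s] = sub.loc[sub.mean(axis=1).idxmax()]
            collapsed[s] = len(rows)
    values = pd.DataFrame(out_rows).T
    values.columns = dataset.values.columns
    out = ExpressionDataset(values, dict(dataset.group_of))
    return PanelSelection(out, found=found, missing=missing, collapsed=collapsed)
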
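"""Condition-specific coexpression networks and Pajek export.

Strongly coexpressed pairs (coexpression level >= the optimal threshold) are
partitioned into three undirected networks: *common* connections are strong
in both groups; *disease-specific* and *normal-specific* connections are the
remaining strong pairs of each group after removing the common ones. For
display, each network's coexpression levels are linearly rescaled to edge
thicknesses in [1, 6] between the threshold and that network's own maximum
level, and the networks are written as Pajek .net files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .coexpression import CoexpressionTable

logger = logging.getLogger(__name__)

EDGE_COLUMNS = (
    "gene_a", "gene_b", "r_disease", "r_normal", "c_used", "thickness", "class"
)


def edge_thickness(c: float | np.ndarray, c_star: float, c_max: float):
    """Linear map of coexpression levels [c_star, c_max] onto [1, 6].

    The threshold level maps to thickness 1 and the maximum level to 6. When
    all levels coincide with the threshold (c_max == c_star) every thickness
    is 1 (degenerate single-level network, logged).
    """
    c = np.asarray(c, dtype=float)
    if c_max < c_star:
        raise ValueError("c_max must be >= c_star")
    if np.any(c < c_star - 1e-12) or np.any(c > c_max + 1e-12):
        raise ValueError("coexpression level outside [c_star, c_max]")
    if c_max == c_star:
        logger.warning("degenerate network: all levels equal the threshold; thickness=1")
        out = np.ones_like(c)
    else:
        out = 1.0 + 5.0 * (c - c_star) / (c_max - c_star)
    return float(out) if out.ndim == 0 else out


@dataclass
class NetworkPartition:
    """Common / normal-specific / disease-specific edge sets with thickness.

    Each edge frame has columns ``gene_a, gene_b, r_disease, r_normal,
    c_used, thickness, class`` where ``c_used`` is the coexpression level
    driving the display thickness: the group's own level for the specific
    networks, max(C_d, C_n) for the common network.
    """

    common: pd.DataFrame
    normal_specific: pd.DataFrame
    disease_specific: pd.DataFrame
    c_star: float

    def edge_sets(self) -> dict[str, pd.DataFrame]:
        return {
            "common": self.common,
            "normal_specific": self.normal_specific,
            "disease_specific": self.disease_specific,
        }

    def edge_list(self) -> pd.DataFrame:
        """All edges of the three networks in one frame."""
        frames = [df for df in self.edge_sets().values() if not df.empty]
        if not frames:
            return pd.DataFrame(columns=list(EDGE_COLUMNS))
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> dict[str, int]:
        return {name: len(df) for name, df in self.edge_sets().items()}


def partition(table: CoexpressionTable, c_star: float) -> NetworkPartition:
    """Split strong pairs into common and condition-specific networks.

    Conservation identities hold by construction:
    ``|common| + |disease_specific|`` equals the number of disease-strong
    pairs and ``|common| + |normal_specific|`` the number of normal-strong
    pairs; weak-in-both pairs appear in no network.
    """
    df = table.defined()
    strong_d = df["c_disease"] >= c_star
    strong_n = df["c_normal"] >= c_star

    def build(mask: pd.Series, c_used: pd.Series, cls: str) -> pd.DataFrame:
        sub = df[mask].copy()
        sub["c_used"] = c_used[mask]
        sub["class"] = cls
        if sub.empty:
            sub["thickness"] = pd.Series(dtype=float)
        else:
            c_max = float(sub["c_used"].max())
            sub["thickness"] = edge_thickness(sub["c_used"].to_numpy(), c_star, c_max)
        return sub[list(EDGE_COLUMNS)].reset_index(drop=True)

    common = build(strong_d & strong_n, df[["c_disease", "c_normal"]].max(axis=1),
                   "common")
    normal_specific = build(strong_n & ~strong_d, df["c_normal"], "normal_specific")
    disease_specific = build(strong_d & ~strong_n, df["c_disease"], "disease_specific")
    return NetworkPartition(
        common=common,
        normal_specific=normal_specific,
        disease_specific=disease_specific,
        c_star=c_star,
    )


def write_pajek(
    edges: pd.DataFrame,
    path: str | Path,
    *,
    all_genes: list[str] | None = None,
    allow_empty: bool = True,
) -> None:
    """Write an undirected network as a Pajek .net file.

    Vertices are the genes incident to at least one edge (or ``all_genes``
    when given), sorted, numbered from 1, with quoted labels; edges go into
    the ``*Edges`` section as ``i j w`` with the thickness as weight.
    """
    if edges.empty and not allow_empty:
        raise ValueError("refusing to write an empty network (allow_empty=False)")
    genes = sorted(
        set(all_genes)
        if all_genes is not None
        else set(edges["gene_a"]) | set(edges["gene_b"])
    )
    index = {g: i + 1 for i, g in enumerate(genes)}
    lines = [f"*Vertices {len(genes)}"]
    lines += [f'{index[g]} "{g}"' for g in genes]
    lines.append("*Edges")
    for row in edges.itertuples(index=False):
        lines.append(f"{index[row.gene_a]} {index[row.gene_b]} {row.thickness:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pajek(path: str | Path) -> pd.DataFrame:
    """Read back a .net file written by :func:`write_pajek`.

    Returns a frame with ``gene_a, gene_b, thickness`` in canonical pair
    order; inverse of the writer up to float formatting.
    """
    labels: dict[int, str] = {}
    rows = []
    section = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        low = line.lower()
        if low.startswith("*vertices"):
            section = "vertices"
            continue
        if low.startswith("*edges") or low.startswith("*arcs"):
            section = "edges"
            continue
        if section == "vertices":
            num, label = line.split(None, 1)
            labels[int(num)] = label.strip().strip('"')
        elif section == "edges":
            i, j, *rest = line.split()
            w = float(rest[0]) if rest else 1.0
            a, b = sorted((labels[int(i)], labels[int(j)]))
            rows.append((a, b, w))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "thickness"])


def degree_report(edges: pd.DataFrame) -> pd.Series:
    """Connection count per gene, sorted descending (hubs first)."""
    if edges.empty:
        return pd.Series(dtype=int, name="degree")
    counts = pd.concat([edges["gene_a"], edges["gene_b"]]).value_counts()
    counts.name = "degree"
    counts.index.name = "gene"
    return counts.sort_values(ascending=False, kind="stable")
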
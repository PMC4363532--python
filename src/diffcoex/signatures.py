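"""miRNA / TF regulatory signatures over a coexpression network.

A miRNA regulatory signature (MRS) is a miRNA together with the strongly
coexpressed gene pairs whose *both* genes are among its putative 3'-UTR
targets; a TF regulatory signature (TRS) is the analogue for a transcription
factor's 5'-UTR binding-site targets. A regulator is selected when it covers
at least ``min_pairs`` network pairs (default 4, inclusive). Signatures of
one class that share at least one gene are merged (connected components of
the gene-overlap relation); the pairwise intersection of a merged MRS and a
merged TRS network is the composite regulatory signature (CRS), to which
every regulator whose target set covers all CRS genes is attached.

Regulator-to-target annotations are plain input tables — this module never
queries a live prediction resource.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

MIRNA = "miRNA"
TF = "TF"

Pair = tuple[str, str]


def _canonical(pair: Sequence[str]) -> Pair:
    a, b = pair
    return (a, b) if a <= b else (b, a)


def _as_pairs(network: pd.DataFrame | Iterable[Sequence[str]]) -> set[Pair]:
    if isinstance(network, pd.DataFrame):
        return {_canonical(t) for t in zip(network["gene_a"], network["gene_b"])}
    return {_canonical(p) for p in network}


@dataclass(frozen=True)
class RegulatorAnnotation:
    """A regulator (miRNA or TF) with its putative target gene set."""

    regulator_id: str
    regulator_class: str  # MIRNA or TF
    targets: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", frozenset(self.targets))
        if self.regulator_class not in (MIRNA, TF):
            raise ValueError(
                f"regulator_class must be {MIRNA!r} or {TF!r}, "
                f"got {self.regulator_class!r}"
            )
        if not self.targets:
            raise ValueError(f"regulator {self.regulator_id!r} has no targets")


@dataclass
class SignatureNetwork:
    """Regulators linked to the network pairs they jointly cover."""

    regulators: dict[str, str]  # regulator id -> class
    covered_pairs: set[Pair]
    merged: bool = False

    @property
    def genes(self) -> set[str]:
        return {g for pair in self.covered_pairs for g in pair}

    @property
    def n_pairs(self) -> int:
        return len(self.covered_pairs)


def read_annotations(path: str | Path) -> list[RegulatorAnnotation]:
    """Read a tab-delimited (regulator_id, class, target_symbol) table."""
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["regulator_id", "regulator_class", "target"],
        dtype=str,
    )
    out = []
    for (rid, cls), grp in df.groupby(
        ["regulator_id", "regulator_class"], sort=True
    ):
        out.append(RegulatorAnnotation(rid, cls, frozenset(grp["target"])))
    return out


def covered_pairs(
    network: pd.DataFrame | Iterable[Sequence[str]],
    annotation: RegulatorAnnotation,
    *,
    both_endpoints: bool = True,
) -> set[Pair]:
    """Network pairs covered by one regulator.

    By default a pair is covered when *both* endpoint genes are targets of
    the regulator; ``both_endpoints=False`` relaxes to at least one endpoint.
    """
    pairs = _as_pairs(network)
    t = annotation.targets
    if both_endpoints:
        return {p for p in pairs if p[0] in t and p[1] in t}
    return {p for p in pairs if p[0] in t or p[1] in t}


def select_signatures(
    network: pd.DataFrame | Iterable[Sequence[str]],
    annotations: Sequence[RegulatorAnnotation],
    min_pairs: int = 4,
    *,
    both_endpoints: bool = True,
) -> tuple[list[SignatureNetwork], pd.DataFrame]:
    """One signature per regulator covering >= ``min_pairs`` network pairs.

    The threshold is inclusive ("no less than"). Returns the selected
    signatures plus a report of every regulator with its covered pair and
    gene counts and selection status.
    """
    if min_pairs < 1:
        raise ValueError("min_pairs must be >= 1")
    selected: list[SignatureNetwork] = []
    report_rows = []
    for ann in annotations:
        pairs = covered_pairs(network, ann, both_endpoints=both_endpoints)
        genes = {g for p in pairs for g in p}
        keep = len(pairs) >= min_pairs
        report_rows.append(
            (ann.regulator_id, ann.regulator_class, len(pairs), len(genes),
             "yes" if keep else "no")
        )
        if keep:
            selected.append(
                SignatureNetwork(
                    regulators={ann.regulator_id: ann.regulator_class},
                    covered_pairs=pairs,
                )
            )
    report = pd.DataFrame(
        report_rows,
        columns=["regulator", "class", "n_covered_pairs", "n_covered_genes",
                 "selected"],
    )
    return selected, report


def merge_signatures(
    signatures: Sequence[SignatureNetwork],
    by_class: str | None = None,
) -> list[SignatureNetwork]:
    """Merge signatures that share at least one gene.

    Connected components of the gene-overlap relation are each emitted as one
    merged network (union of regulators and covered pairs); the result is
    independent of the input order. ``by_class`` restricts and checks the
    regulator class.
    """
    sigs = list(signatures)
    if by_class is not None:
        for s in sigs:
            if set(s.regulators.values()) - {by_class}:
                raise ValueError(f"signature of class other than {by_class!r}")
    g = nx.Graph()
    g.add_nodes_from(range(len(sigs)))
    for i in range(len(sigs)):
        for j in range(i + 1, len(sigs)):
            if sigs[i].genes & sigs[j].genes:
                g.add_edge(i, j)
    merged = []
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        regulators: dict[str, str] = {}
        pairs: set[Pair] = set()
        for k in comp:
            regulators.update(sigs[k].regulators)
            pairs |= sigs[k].covered_pairs
        merged.append(
            SignatureNetwork(regulators=regulators, covered_pairs=pairs,
                             merged=len(comp) > 1)
        )
    # deterministic order: by sorted regulator ids
    merged.sort(key=lambda s: sorted(s.regulators))
    return merged


def composite_signature(
    mrs: SignatureNetwork,
    trs: SignatureNetwork,
    annotations: Sequence[RegulatorAnnotation] = (),
) -> SignatureNetwork:
    """Composite regulatory signature: the MRS/TRS pair intersection.

    Covered pairs are those present in both networks; attached regulators are
    the regulators of either network whose target set covers every CRS gene
    (when ``annotations`` provides target sets; otherwise the regulators of
    both networks are carried over only if the CRS is their full network).
    An empty intersection yields an empty, valid CRS.
    """
    pairs = mrs.covered_pairs & trs.covered_pairs
    genes = {g for p in pairs for g in p}
    targets_of = {a.regulator_id: a.targets for a in annotations}
    regulators: dict[str, str] = {}
    for source in (mrs, trs):
        for rid, cls in source.regulators.items():
            t = targets_of.get(rid)
            if t is not None:
                if genes and genes <= t:
                    regulators[rid] = cls
            else:
                covered = {p for p in source.covered_pairs if set(p) <= genes}
                if genes and covered == pairs:
                    regulators[rid] = cls
    return SignatureNetwork(regulators=regulators, covered_pairs=pairs, merged=True)


def signature_report(signatures: Sequence[SignatureNetwork]) -> pd.DataFrame:
    rows = [
        (";".join(sorted(s.regulators)), s.n_pairs, len(s.genes), s.merged)
        for s in signatures
    ]
    return pd.DataFrame(
        rows, columns=["regulators", "n_pairs", "n_genes", "merged"]
    )


def write_signature_pajek(signature: SignatureNetwork, path: str | Path) -> None:
    """Write a signature as a bipartite-style Pajek file.

    Gene vertices first, regulator vertices (suffixed with their class)
    after; gene-gene covered pairs and regulator->gene target links all go
    in the *Edges section with weight 1.
    """
    genes = sorted(signature.genes)
    regs = sorted(signature.regulators)
    index = {g: i + 1 for i, g in enumerate(genes)}
    for r in regs:
        index[r] = len(index) + 1
    lines = [f"*Vertices {len(index)}"]
    lines += [f'{index[g]} "{g}"' for g in genes]
    lines += [f'{index[r]} "{r} ({signature.regulators[r]})"' for r in regs]
    lines.append("*Edges")
    for a, b in sorted(signature.covered_pairs):
        lines.append(f"{index[a]} {index[b]} 1")
    for r in regs:
        for g in genes:
            lines.append(f"{index[r]} {index[g]} 1")
    Path(path).write_text("\n".join(lines) + "\n")


def demo_annotations() -> list[RegulatorAnnotation]:
    """Synthetic demonstration annotations for the worked example.

    Regulator ids follow the normal-specific signatures discussed in the
    study's results (hsa-miR-504, hsa-miR-125a, AP-4, E2F, VDR); target sets
    are synthetic fill-ins chosen so that the documented behaviours appear:
    the two miRNA signatures share BAK1 and BCL2 and merge, the three TF
    signatures share E2F2 and merge, and the MRS/TRS intersection is the
    E2F2-BAK1-PIK3R5 triangle covered by AP-4 and hsa-miR-125a. They are a
    demonstration fixture, not curated target predictions.
    """
    return [
        RegulatorAnnotation("hsa-miR-504", MIRNA,
                            frozenset({"BAK1", "BCL2", "E2F1", "MCL1"})),
        RegulatorAnnotation("hsa-miR-125a", MIRNA,
                            frozenset({"BAK1", "BCL2", "E2F2", "PIK3R5"})),
        RegulatorAnnotation("AP-4", TF,
                            frozenset({"BAK1", "BAD", "PIK3R2", "PIK3R5", "E2F2"})),
        RegulatorAnnotation("E2F", TF,
                            frozenset({"E2F1", "E2F2", "E2F3", "MYC", "BCL2"})),
        RegulatorAnnotation("VDR", TF,
                            frozenset({"E2F2", "AKT3", "BAX", "BECN1"})),
        # below the default min_pairs threshold on the demo network
        RegulatorAnnotation("hsa-miR-15a", MIRNA,
                            frozenset({"E2F3", "AKT3", "MYC"})),
    ]


def demo_network_pairs() -> set[Pair]:
    """Synthetic normal-specific strong-pair set for the worked example.

    Built so each selected demo regulator covers at least four pairs and the
    composite signature is exactly the E2F2/BAK1/PIK3R5 triangle.
    """
    edges = [
        # hsa-miR-504 coverage (targets BAK1, BCL2, E2F1, MCL1): 4 pairs
        ("BAK1", "BCL2"), ("BAK1", "E2F1"), ("E2F1", "MCL1"), ("BCL2", "MCL1"),
        # hsa-miR-125a coverage (BAK1, BCL2, E2F2, PIK3R5): adds the triangle
        ("E2F2", "BAK1"), ("E2F2", "PIK3R5"), ("BAK1", "PIK3R5"),
        # AP-4 coverage (BAK1, BAD, PIK3R2, PIK3R5, E2F2): triangle + 2 more
        ("BAD", "PIK3R2"), ("E2F2", "BAD"),
        # E2F coverage (E2F1, E2F2, E2F3, MYC, BCL2): 4 pairs
        ("E2F1", "E2F2"), ("E2F2", "MYC"), ("E2F3", "MYC"), ("E2F2", "E2F3"),
        # VDR coverage (E2F2, AKT3, BAX, BECN1): 4 pairs
        ("E2F2", "AKT3"), ("AKT3", "BAX"), ("BAX", "BECN1"), ("E2F2", "BECN1"),
    ]
    return {_canonical(e) for e in edges}
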
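"""Model/Results facade for the differential coexpression analysis.

:class:`DifferentialCoexpression` is built from an expression dataset (or a
gene-by-sample DataFrame plus group labels); :meth:`~DifferentialCoexpression.fit`
runs the estimation — per-group coexpression of all gene pairs, KS-optimal
threshold selection, chi-square verification, network partition — and
returns a :class:`DifferentialCoexpressionResults` carrying the estimates,
diagnostics, a ``summary()`` table and export/plot helpers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import network as _network
from . import signatures as _signatures
from .coexpression import CoexpressionTable, coexpression_table
from .datasets import DISEASE, NORMAL, ExpressionDataset, GenePanel, select_panel
from .threshold import ThresholdResult, find_threshold


class DifferentialCoexpression:
    """Two-group differential gene-coexpression network model.

    Parameters
    ----------
    dataset : ExpressionDataset
        Gene-by-sample expression values with disease/normal group labels.
    panel : GenePanel, optional
        Restrict the analysis to a gene panel (probes collapsed per
        ``collapse``); by default all rows are used.
    """

    def __init__(
        self,
        dataset: ExpressionDataset,
        panel: GenePanel | None = None,
        *,
        collapse: str = "max_mean",
    ) -> None:
        if panel is not None:
            sel = select_panel(dataset, panel, collapse=collapse)  # type: ignore[arg-type]
            dataset = sel.dataset
            self.panel_selection = sel
        else:
            self.panel_selection = None
        self.dataset = dataset

    @classmethod
    def from_dataframe(
        cls,
        values: pd.DataFrame,
        groups: Mapping[str, str],
        panel: Sequence[str] | GenePanel | None = None,
        **kwargs,
    ) -> "DifferentialCoexpression":
        """Build from a gene-by-sample DataFrame and a sample->group map."""
        if panel is not None and not isinstance(panel, GenePanel):
            panel = GenePanel(tuple(panel))
        return cls(ExpressionDataset(values, dict(groups)), panel=panel, **kwargs)

    def fit(self, grid: str | float = "observed") -> "DifferentialCoexpressionResults":
        """Estimate the optimal threshold and partition the networks.

        ``grid`` selects the candidate-threshold grid: ``"observed"`` (exact;
        the union of all observed coexpression levels) or a uniform step
        width such as ``0.0001``.
        """
        table = coexpression_table(self.dataset)
        thr = find_threshold(table, grid=grid)
        part = _network.partition(table, thr.c_star)
        return DifferentialCoexpressionResults(self, table, thr, part)


class DifferentialCoexpressionResults:
    """Fitted differential-coexpression estimates and diagnostics.

    Attributes
    ----------
    table : CoexpressionTable
        Signed correlations and coexpression levels of every gene pair.
    threshold : ThresholdResult
        Optimal threshold C*, KS deviation D and p-value, contingency table,
        chi-square statistic.
    partition : NetworkPartition
        Common / normal-specific / disease-specific edge sets with [1, 6]
        display thicknesses.
    """

    def __init__(
        self,
        model: DifferentialCoexpression,
        table: CoexpressionTable,
        threshold: ThresholdResult,
        partition: _network.NetworkPartition,
    ) -> None:
        self.model = model
        self.table = table
        self.threshold = threshold
        self.partition = partition

    # -- headline estimates ------------------------------------------------
    @property
    def c_star(self) -> float:
        """Optimal (disease-associated) coexpression threshold."""
        return self.threshold.c_star

    @property
    def ks_statistic(self) -> float:
        """Maximum deviation D between the two inverted CDFs."""
        return self.threshold.d

    @property
    def ks_pvalue(self) -> float:
        return self.threshold.ks_p

    @property
    def chi2(self) -> float:
        return self.threshold.chi2

    @property
    def chi2_pvalue(self) -> float:
        return self.threshold.chi2_p

    def summary(self) -> str:
        """Human-readable estimation summary (4-d.p. display)."""
        d = self.model.dataset
        counts = self.partition.summary()
        lines = [
            "Differential coexpression network analysis",
            "==========================================",
            f"genes: {d.n_genes}   samples: {d.n_samples} "
            f"({len(d.samples_in(DISEASE))} disease + {len(d.samples_in(NORMAL))} normal)",
            f"gene pairs: {self.table.n_pairs}"
            + (f" ({self.table.n_excluded} excluded, undefined correlation)"
               if self.table.n_excluded else ""),
            "",
            self.threshold.report(),
            "",
            "Network partition",
            "-----------------",
            f"common            : {counts['common']} edges",
            f"normal-specific   : {counts['normal_specific']} edges",
            f"disease-specific  : {counts['disease_specific']} edges",
        ]
        hubs = _network.degree_report(self.partition.normal_specific).head(3)
        if len(hubs):
            top = ", ".join(f"{g} ({int(k)})" for g, k in hubs.items())
            lines.append(f"normal-specific hubs: {top}")
        return "\n".join(lines)

    def degree_report(self, which: str = "normal_specific") -> pd.Series:
        """Per-gene connection counts for one network (hubs first)."""
        return _network.degree_report(self.partition.edge_sets()[which])

    # -- signatures --------------------------------------------------------
    def signatures(
        self,
        annotations: Sequence[_signatures.RegulatorAnnotation],
        which: str = "normal_specific",
        min_pairs: int = 4,
        *,
        both_endpoints: bool = True,
    ):
        """Regulatory-signature stage over one partition network.

        Returns ``(merged_mrs, merged_trs, crs_list, report)``: the merged
        miRNA and TF signature networks, the composite signature of each
        MRS x TRS combination with a non-empty intersection, and the
        per-regulator selection report.
        """
        edges = self.partition.edge_sets()[which]
        selected, report = _signatures.select_signatures(
            edges, annotations, min_pairs=min_pairs, both_endpoints=both_endpoints
        )
        mrs = _signatures.merge_signatures(
            [s for s in selected
             if set(s.regulators.values()) == {_signatures.MIRNA}],
        )
        trs = _signatures.merge_signatures(
            [s for s in selected
             if set(s.regulators.values()) == {_signatures.TF}],
        )
        crs = []
        for m in mrs:
            for t in trs:
                c = _signatures.composite_signature(m, t, annotations)
                if c.covered_pairs:
                    crs.append(c)
        return mrs, trs, crs, report

    # -- export ------------------------------------------------------------
    def to_pajek(self, outdir: str | Path, *, include_all_genes: bool = False) -> list[Path]:
        """Write common.net, normal_specific.net, disease_specific.net."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        all_genes = self.model.dataset.gene_symbols if include_all_genes else None
        written = []
        for name, edges in self.partition.edge_sets().items():
            path = outdir / f"{name}.net"
            _network.write_pajek(edges, path, all_genes=all_genes)
            written.append(path)
        return written

    def plot_survival_curves(self, ax=None):
        """Step plot of the two inverted CDFs with C* marked (Fig. 1 style)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.threshold.curve
        ax.step(c.thresholds, c.f_disease, where="post", label="disease")
        ax.step(c.thresholds, c.f_normal, where="post", label="normal")
        ax.axvline(self.c_star, color="k", ls="--", lw=0.8,
                   label=f"C* = {self.c_star:.4f}")
        ax.set_xlabel("coexpression threshold")
        ax.set_ylabel("fraction of pairs at/above threshold")
        ax.legend()
        return ax
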
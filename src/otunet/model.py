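"""Model/Results interface tying clustering, AIC selection and ecology together.

``OtuThresholdModel`` holds a dereplicated sequence-type table and the scoring
configuration; ``fit()`` computes pairwise distances, cuts one average-linkage
tree across the threshold grid, scores every partition's bipartite OTU-plot
network by AIC, and returns an ``OtuThresholdResults`` carrying the AIC curve,
the selected threshold and partition, and the downstream ecology statistics.

Example
-------
>>> from otunet import OtuThresholdModel
>>> model = OtuThresholdModel.from_fasta("reads.fasta", sample_map="mapping.tsv")
>>> res = model.fit()
>>> res.optimal_threshold, res.k_optimal
(76, 16)
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from . import clustering, ecology, io_seq, network_aic


class OtuThresholdModel:
    """AIC-guided selection of an OTU clustering threshold.

    Parameters
    ----------
    table
        Dereplicated sequence types with per-plot abundances.
    grid
        Strictly increasing integer similarity percentages (default 74..99).
    abundance_model
        "poisson" (default) or "binomial" for the abundance layer.
    weighted
        Select on the abundance-weighted AIC (default) or binary-only AIC.
    verbatim_sign
        Use the published (sign-flipped) binary log-likelihood exponent.
    """

    def __init__(
        self,
        table: io_seq.SequenceTypeTable,
        grid: Sequence[int] = clustering.DEFAULT_GRID,
        abundance_model: str = "poisson",
        weighted: bool = True,
        verbatim_sign: bool = False,
    ) -> None:
        if abundance_model not in network_aic.ABUNDANCE_MODELS:
            raise ValueError(f"unknown abundance model {abundance_model!r}")
        self.table = table
        self.grid = tuple(int(g) for g in grid)
        self.abundance_model = abundance_model
        self.weighted = weighted
        self.verbatim_sign = verbatim_sign

    @classmethod
    def from_fasta(
        cls,
        path: str | Path,
        sample_map: Mapping[str, str] | str | Path | None = None,
        header_regex: str | None = None,
        min_length: int = 1,
        trim_to: int | None = None,
        **kwargs,
    ) -> "OtuThresholdModel":
        """Build the model straight from a FASTA file plus read-to-plot mapping."""
        result = io_seq.read_fasta(path, sample_map=sample_map, header_regex=header_regex)
        table = io_seq.dereplicate(result.records, min_length=min_length, trim_to=trim_to)
        return cls(table, **kwargs)

    @classmethod
    def from_table(cls, path: str | Path, **kwargs) -> "OtuThresholdModel":
        """Build the model from a sequence-type abundance table TSV."""
        return cls(io_seq.read_table(path), **kwargs)

    def fit(self) -> "OtuThresholdResults":
        """Scan the grid, score each partition's network, select the AIC minimum."""
        dm = clustering.compute_distances(self.table)
        cluster_scan = clustering.scan(dm, self.table, self.grid)
        curve = network_aic.aic_curve(
            self.table,
            cluster_scan,
            model=self.abundance_model,
            weighted=self.weighted,
            verbatim_sign=self.verbatim_sign,
        )
        return OtuThresholdResults(self, dm, cluster_scan, curve)


class OtuThresholdResults:
    """Fitted threshold selection: AIC curve, optimal partition, ecology views."""

    def __init__(
        self,
        model: OtuThresholdModel,
        distances: clustering.DistanceMatrix,
        cluster_scan: clustering.ClusterScan,
        curve: network_aic.AicCurve,
    ) -> None:
        self.model = model
        self.distances = distances
        self.scan = cluster_scan
        self.aic_curve = curve
        self.optimal_threshold = curve.optimal_threshold
        self.optimal_partition = next(
            p for p in cluster_scan if p.threshold_pct == self.optimal_threshold
        )
        self.network = network_aic.build_network(model.table, self.optimal_partition)

    @property
    def k_optimal(self) -> int:
        return self.optimal_partition.k

    def curve_frame(self) -> pd.DataFrame:
        return self.aic_curve.to_frame()

    def partition_at(self, threshold_pct: int) -> clustering.Partition:
        for p in self.scan:
            if p.threshold_pct == threshold_pct:
                return p
        raise KeyError(f"threshold {threshold_pct} not in the fitted grid")

    def network_at(self, threshold_pct: int) -> network_aic.BipartiteNetwork:
        return network_aic.build_network(
            self.model.table, self.partition_at(threshold_pct)
        )

    # ---- ecology views on the optimal network -------------------------------

    def otu_profiles(self, generalist_min: int = 6) -> list[ecology.OtuProfile]:
        return ecology.classify_otus(self.network, generalist_min=generalist_min)

    def plot_summaries(self, generalist_min: int = 6) -> list[ecology.PlotSummary]:
        return ecology.plot_summaries(
            self.network,
            self.otu_profiles(generalist_min),
            plot_labels=self.model.table.plots,
        )

    def cooccurrence(
        self, mode: Literal["jaccard", "min"] = "jaccard"
    ) -> ecology.CooccurrenceMatrix:
        return ecology.cooccurrence(
            self.network, mode=mode, plot_labels=self.model.table.plots
        )

    def plot_dendrogram(
        self, mode: Literal["jaccard", "min"] = "jaccard"
    ) -> ecology.PlotDendrogram:
        return ecology.cluster_plots(self.cooccurrence(mode))

    def specialist_gradient(
        self, doses: Sequence[float], generalist_min: int = 6
    ) -> pd.DataFrame:
        return ecology.specialist_gradient(self.plot_summaries(generalist_min), doses)

    def export_network(
        self, path: str | Path, fmt: Literal["edgelist", "gml"] = "edgelist",
        generalist_min: int = 6,
    ):
        return ecology.export_network(
            self.network,
            self.otu_profiles(generalist_min),
            path,
            fmt=fmt,
            plot_labels=self.model.table.plots,
        )

    def plot_aic(self, ax=None):
        """AIC-vs-threshold line plot (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        frame = self.curve_frame()
        col = self.aic_curve.selection
        ax.plot(frame["threshold_pct"], frame[col], marker="o")
        ax.axvline(self.optimal_threshold, linestyle="--", color="grey")
        ax.set_xlabel("similarity threshold (%)")
        ax.set_ylabel(col)
        return ax

    def summary(self) -> str:
        """Plain-text summary table of the fitted threshold selection."""
        t = self.model.table
        profiles = self.otu_profiles(min(6, t.n_plots))
        n_gen = sum(1 for p in profiles if p.otu_class == "generalist")
        n_spec = sum(1 for p in profiles if p.otu_class == "specialist")
        n_single = sum(1 for p in profiles if p.is_singleton)
        sel = self.aic_curve.selection
        best = next(
            x for x in self.aic_curve.results
            if x.threshold_pct == self.optimal_threshold
        )
        lines = [
            "          OTU threshold selection (bipartite network AIC)",
            "=" * 66,
            f"Sequence types:     {t.n_types:>8}    Plots:            {t.n_plots:>8}",
            f"Total reads:        {t.total_reads:>8}    Grid:        {self.grid_label():>13}",
            f"Abundance model:    {self.model.abundance_model:>8}    Selection:   {sel:>13}",
            "-" * 66,
            f"Optimal threshold:  {self.optimal_threshold:>7}%    OTUs at optimum:  {self.k_optimal:>8}",
            f"AIC (binary):       {best.aic_binary:>12.3f}    AIC (weighted): {best.aic_weighted:>12.3f}",
            f"log L (binary):     {best.ll_binary:>12.3f}    log L (abund.): {best.ll_abund:>12.3f}",
            "-" * 66,
            f"Generalist OTUs:    {n_gen:>8}    Specialist OTUs:  {n_spec:>8}",
            f"Singleton OTUs:     {n_single:>8}    Links (L):        {self.network.L_total:>8}",
            "=" * 66,
        ]
        return "\n".join(lines)

    def grid_label(self) -> str:
        g = self.model.grid
        step = g[1] - g[0] if len(g) > 1 else 1
        contiguous = all(b - a == step for a, b in zip(g, g[1:]))
        return f"{g[0]}..{g[-1]}" + ("" if contiguous and step == 1 else f" ({len(g)} pts)")

    @property
    def grid(self) -> tuple[int, ...]:
        return self.model.grid
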
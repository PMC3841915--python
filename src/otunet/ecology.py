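"""Community statistics on the optimal OTU-plot network.

Occupancy-based classes follow the field's occupancy definitions: an OTU is a
*generalist* if it occurs in at least ``generalist_min`` plots (default 6,
mirroring an 8-plot design; a fractional rule >= 0.75*r is available for
other designs), a *specialist* (endemic) if it occurs in exactly one plot,
and a *singleton* if it is represented by a single read in a single plot.
Per-plot summaries tally total reads, distinct OTUs, endemics, singletons and
the reads carried by generalist and endemic OTUs.  Co-occurrence between two
plots is the fraction of OTUs shared (Jaccard by default: shared/union; a
shared/min variant is available), and plots are grouped by complete-linkage
clustering of 1 - co-occurrence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from skbio import TreeNode

from .network_aic import BipartiteNetwork

logger = logging.getLogger(__name__)

OtuClass = Literal["generalist", "intermediate", "specialist"]


@dataclass
class OtuProfile:
    """Occupancy, abundance and class of one OTU."""

    otu_id: int
    abundance: np.ndarray  # (r,) per-plot summed abundance
    occupancy: int
    total_abundance: int
    otu_class: OtuClass
    is_singleton: bool


def classify_otus(net: BipartiteNetwork, generalist_min: int = 6) -> list[OtuProfile]:
    """Classify every OTU as generalist / intermediate / specialist."""
    if not 1 <= generalist_min <= net.r:
        raise ValueError(f"generalist_min must lie in [1, {net.r}]")
    profiles = []
    for i in range(net.k):
        row = net.a_dot_iq[i]
        occ = int((row > 0).sum())
        total = int(row.sum())
        if occ >= generalist_min:
            cls: OtuClass = "generalist"
        elif occ == 1:
            cls = "specialist"
        else:
            cls = "intermediate"
        profiles.append(
            OtuProfile(
                otu_id=i,
                abundance=row.copy(),
                occupancy=occ,
                total_abundance=total,
                otu_class=cls,
                is_singleton=(total == 1),
            )
        )
    return profiles


def fractional_generalist_min(r: int, fraction: float = 0.75) -> int:
    """Occupancy cutoff >= fraction*r, for designs with other plot counts."""
    return max(1, int(np.ceil(fraction * r)))


@dataclass
class PlotSummary:
    """Per-plot community tallies (reads, OTUs, endemics, singletons, classes)."""

    plot_label: str
    total_sequences: int
    unique_otus: int
    endemic_otus: int
    singletons: int
    generalist_sequences: int
    endemic_sequences: int


def plot_summaries(
    net: BipartiteNetwork,
    profiles: Sequence[OtuProfile],
    plot_labels: Sequence[str] | None = None,
) -> list[PlotSummary]:
    """Tally each plot's reads, OTU richness, endemics and class abundances."""
    if len(profiles) != net.k:
        raise ValueError("profiles do not match the network")
    labels = list(plot_labels) if plot_labels is not None else [
        f"plot_{q + 1}" for q in range(net.r)
    ]
    out = []
    for q in range(net.r):
        col = net.a_dot_iq[:, q]
        present = col > 0
        endemic_here = [
            p for p in profiles if p.otu_class == "specialist" and p.abundance[q] > 0
        ]
        out.append(
            PlotSummary(
                plot_label=labels[q],
                total_sequences=int(col.sum()),
                unique_otus=int(present.sum()),
                endemic_otus=len(endemic_here),
                singletons=sum(1 for p in endemic_here if p.is_singleton),
                generalist_sequences=int(
                    sum(p.abundance[q] for p in profiles if p.otu_class == "generalist")
                ),
                endemic_sequences=int(sum(p.abundance[q] for p in endemic_here)),
            )
        )
    return out


def summaries_frame(summaries: Sequence[PlotSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "plot": [s.plot_label for s in summaries],
            "total_sequences": [s.total_sequences for s in summaries],
            "unique_otus": [s.unique_otus for s in summaries],
            "endemic_otus": [s.endemic_otus for s in summaries],
            "singletons": [s.singletons for s in summaries],
            "generalist_sequences": [s.generalist_sequences for s in summaries],
            "endemic_sequences": [s.endemic_sequences for s in summaries],
        }
    )


def profiles_frame(profiles: Sequence[OtuProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "otu_id": [p.otu_id for p in profiles],
            "occupancy": [p.occupancy for p in profiles],
            "total_abundance": [p.total_abundance for p in profiles],
            "class": [p.otu_class for p in profiles],
            "is_singleton": [p.is_singleton for p in profiles],
        }
    )


@dataclass
class CooccurrenceMatrix:
    """Symmetric r x r matrix of shared-OTU fractions between plots."""

    values: np.ndarray
    plot_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.allclose(self.values, self.values.T):
            raise ValueError("co-occurrence matrix must be symmetric")

    def write(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.plot_labels, columns=self.plot_labels).to_csv(
            path, sep="\t"
        )


def cooccurrence(
    net: BipartiteNetwork,
    mode: Literal["jaccard", "min"] = "jaccard",
    plot_labels: Sequence[str] | None = None,
) -> CooccurrenceMatrix:
    """Fraction of OTUs shared between each pair of plots.

    ``jaccard`` divides by the union of the two plots' OTU sets, ``min`` by
    the smaller set.  A plot with no OTUs gets zeros (diagonal included) and
    triggers a warning.
    """
    labels = list(plot_labels) if plot_labels is not None else [
        f"plot_{q + 1}" for q in range(net.r)
    ]
    present = net.a_dot_iq > 0  # (k, r)
    sizes = present.sum(axis=0)
    vals = np.zeros((net.r, net.r))
    for q1 in range(net.r):
        if sizes[q1] == 0:
            warnings.warn(f"plot {labels[q1]!r} contains no OTUs", stacklevel=2)
            continue
        vals[q1, q1] = 1.0
        for q2 in range(q1 + 1, net.r):
            if sizes[q2] == 0:
                continue
            shared = int((present[:, q1] & present[:, q2]).sum())
            if mode == "jaccard":
                denom = int((present[:, q1] | present[:, q2]).sum())
            elif mode == "min":
                denom = int(min(sizes[q1], sizes[q2]))
            else:
                raise ValueError(f"unknown co-occurrence mode {mode!r}")
            vals[q1, q2] = vals[q2, q1] = shared / denom
    return CooccurrenceMatrix(vals, labels)


@dataclass
class PlotDendrogram:
    """Complete-linkage grouping of plots from co-occurrence distances."""

    linkage_matrix: np.ndarray
    plot_labels: list[str]

    def to_newick(self) -> str:
        tree = TreeNode.from_linkage_matrix(self.linkage_matrix, self.plot_labels)
        return str(tree).strip()

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


def cluster_plots(cm: CooccurrenceMatrix) -> PlotDendrogram:
    """Complete-linkage hierarchical clustering of plots on 1 - co-occurrence."""
    r = cm.values.shape[0]
    if r < 2:
        raise ValueError("need at least two plots to cluster")
    dist = 1.0 - cm.values
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    return PlotDendrogram(linkage(condensed, method="complete"), list(cm.plot_labels))


def specialist_gradient(
    summaries: Sequence[PlotSummary], doses: Sequence[float]
) -> pd.DataFrame:
    """Per-plot generalist/specialist read proportions against a dose covariate.

    Returns a frame with columns (plot, dose, proportion_generalist_sequences,
    proportion_specialist_sequences) sorted by dose (stable for ties).
    """
    if len(doses) != len(summaries):
        raise ValueError("doses must align with plots")
    rows = []
    for s, dose in zip(summaries, doses):
        total = s.total_sequences
        rows.append(
            {
                "plot": s.plot_label,
                "dose": float(dose),
                "proportion_generalist_sequences": (
                    s.generalist_sequences / total if total else 0.0
                ),
                "proportion_specialist_sequences": (
                    s.endemic_sequences / total if total else 0.0
                ),
            }
        )
    return (
        pd.DataFrame(rows).sort_values("dose", kind="stable").reset_index(drop=True)
    )


def to_graph(
    net: BipartiteNetwork,
    profiles: Sequence[OtuProfile],
    plot_labels: Sequence[str] | None = None,
) -> nx.Graph:
    """Bipartite OTU/plot graph; edge weight = summed OTU abundance in the plot."""
    labels = list(plot_labels) if plot_labels is not None else [
        f"plot_{q + 1}" for q in range(net.r)
    ]
    g = nx.Graph()
    for p in profiles:
        g.add_node(f"OTU_{p.otu_id}", bipartite=0, otu_class=p.otu_class)
    for q, label in enumerate(labels):
        g.add_node(label, bipartite=1)
    for i in range(net.k):
        for q in range(net.r):
            w = int(net.a_dot_iq[i, q])
            if w > 0:
                g.add_edge(f"OTU_{i}", labels[q], weight=w)
    return g


def export_network(
    net: BipartiteNetwork,
    profiles: Sequence[OtuProfile],
    path: str | Path,
    fmt: Literal["edgelist", "gml"] = "edgelist",
    plot_labels: Sequence[str] | None = None,
) -> nx.Graph:
    """Write the bipartite network as a weighted edge-list TSV or GML file."""
    g = to_graph(net, profiles, plot_labels)
    if fmt == "edgelist":
        with open(path, "w") as fh:
            fh.write("otu\tplot\tweight\n")
            for u, v, data in sorted(g.edges(data=True)):
                a, b = (u, v) if u.startswith("OTU_") else (v, u)
                fh.write(f"{a}\t{b}\t{data['weight']}\n")
    elif fmt == "gml":
        nx.write_gml(g, str(path))
    else:
        raise ValueError(f"unknown export format {fmt!r}")
    return g


def read_edgelist(path: str | Path) -> nx.Graph:
    """Parse an edge-list TSV written by :func:`export_network` (round-trip)."""
    g = nx.Graph()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["otu", "plot", "weight"]:
            raise ValueError(f"{path}:1: malformed edge-list header")
        for line in fh:
            otu, plot, weight = line.rstrip("\n").split("\t")
            g.add_node(otu, bipartite=0)
            g.add_node(plot, bipartite=1)
            g.add_edge(otu, plot, weight=int(weight))
    return g
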
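"""Bipartite OTU-plot network likelihoods and AIC-based threshold selection.

For a partition of S sequence types into k OTUs observed across r plots, the
network is scored in two layers:

* a binary occurrence layer — for OTU i and plot q, the link probability is
  p(iq) = L_iq / S_i where L_iq counts member sequence types present in q and
  S_i is the OTU size; the log-likelihood of the observed links is the
  binomial form L_iq*log(p) + (S_i - L_iq)*log(1-p) with 0*log(0) = 0, and
  AIC_binary = 2kr + 2S - 2*sum(LL).

* an abundance layer — member read counts within an OTU-plot cell are modelled
  as Poisson with mean a_.iq / S_i (the cell total spread evenly over members)
  or Binomial(size=a_.iq, p=1/S_i); AIC_weighted = 4kr + 2S - 2*sum(LL_binary
  + LL_abundance).

Minimising AIC over a grid of clustering thresholds selects the coarsest OTU
definition that still reproduces the observed occupancy and abundance
structure; ties go to the lower threshold (fewer OTUs).

The published binary form carries the exponent (L_iq - S_i) on (1 - p), which
makes that term positive; ``verbatim_sign=True`` reproduces it literally,
while the default uses the standard (S_i - L_iq) sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import xlogy
from scipy.stats import binom, poisson

from .clustering import ClusterScan, Partition
from .io_seq import SequenceTypeTable

ABUNDANCE_MODELS = ("poisson", "binomial")


@dataclass
class BipartiteNetwork:
    """The OTU x plot network induced by a partition of a sequence-type table."""

    k: int
    r: int
    S: int
    S_i: np.ndarray  # (k,) member counts
    L_iq: np.ndarray  # (k, r) link counts: members with abundance > 0
    a_dot_iq: np.ndarray  # (k, r) summed member abundance
    members: list[np.ndarray]  # per OTU: (S_i, r) member abundance rows
    threshold_pct: int | None = None

    def __post_init__(self) -> None:
        if int(self.S_i.sum()) != self.S:
            raise ValueError("sum of S_i must equal S")
        if ((self.L_iq < 0) | (self.L_iq > self.S_i[:, None])).any():
            raise ValueError("L_iq must lie in [0, S_i]")

    @property
    def L_total(self) -> int:
        return int(self.L_iq.sum())


def build_network(table: SequenceTypeTable, partition: Partition) -> BipartiteNetwork:
    """Assemble link counts and abundance blocks for one partition."""
    if partition.assignment.size != table.n_types:
        raise ValueError("partition does not cover the table's sequence types")
    k, r = partition.k, table.n_plots
    members = [table.abundance[partition.members(i)] for i in range(k)]
    S_i = np.array([m.shape[0] for m in members], dtype=np.int64)
    L_iq = np.stack([(m > 0).sum(axis=0) for m in members]) if k else np.zeros((0, r))
    a_dot = np.stack([m.sum(axis=0) for m in members]) if k else np.zeros((0, r))
    return BipartiteNetwork(
        k=k,
        r=r,
        S=table.n_types,
        S_i=S_i,
        L_iq=np.asarray(L_iq, dtype=np.int64),
        a_dot_iq=np.asarray(a_dot, dtype=np.int64),
        members=members,
        threshold_pct=partition.threshold_pct,
    )


def link_probability(net: BipartiteNetwork, i: int, q: int) -> float:
    """p(iq) = L_iq / S_i."""
    return float(net.L_iq[i, q]) / float(net.S_i[i])


def binary_ll_matrix(net: BipartiteNetwork, verbatim_sign: bool = False) -> np.ndarray:
    """Per-cell binary log-likelihoods as a (k, r) array."""
    L = net.L_iq.astype(float)
    S_i = net.S_i.astype(float)[:, None]
    p = L / S_i
    sign = -1.0 if verbatim_sign else 1.0
    return xlogy(L, p) + sign * xlogy(S_i - L, 1.0 - p)


def binary_ll(net: BipartiteNetwork, i: int, q: int, verbatim_sign: bool = False) -> float:
    """Binary log-likelihood contribution of one OTU-plot cell."""
    L = float(net.L_iq[i, q])
    S_i = float(net.S_i[i])
    p = L / S_i
    sign = -1.0 if verbatim_sign else 1.0
    return float(xlogy(L, p) + sign * xlogy(S_i - L, 1.0 - p))


def binary_aic(net: BipartiteNetwork, verbatim_sign: bool = False) -> float:
    """AIC of the binary network: 2kr + 2S - 2*sum of binary log-likelihoods."""
    ll = binary_ll_matrix(net, verbatim_sign).sum()
    return 2.0 * net.k * net.r + 2.0 * net.S - 2.0 * ll


def _abundance_ll_otu(A: np.ndarray, model: str) -> np.ndarray:
    """Per-plot abundance log-likelihood for one OTU's (S_i, r) member block."""
    S_i = A.shape[0]
    a_dot = A.sum(axis=0)
    if model == "poisson":
        lam = a_dot / S_i
        terms = poisson.logpmf(A, lam[None, :])
        # lambda = 0 forces every member count to 0: degenerate cell, LL 0
        terms[:, lam == 0] = 0.0
    elif model == "binomial":
        if S_i == 1:
            return np.zeros(A.shape[1])
        terms = binom.logpmf(A, a_dot[None, :], 1.0 / S_i)
        terms[:, a_dot == 0] = 0.0
    else:
        raise ValueError(f"unknown abundance model {model!r}")
    return terms.sum(axis=0)


def abundance_ll(net: BipartiteNetwork, i: int, q: int, model: str = "poisson") -> float:
    """Abundance log-likelihood of one OTU-plot cell under Poisson or Binomial.

    Poisson sums member log-pmfs at mean a_.iq/S_i over all S_i members,
    zero-abundance members included; Binomial uses size a_.iq and p = 1/S_i
    and is degenerate (contribution 0) when S_i = 1.
    """
    return float(_abundance_ll_otu(net.members[i].astype(float), model)[q])


def abundance_ll_total(net: BipartiteNetwork, model: str = "poisson") -> float:
    """Total abundance log-likelihood over all OTU-plot cells."""
    return float(
        sum(_abundance_ll_otu(m.astype(float), model).sum() for m in net.members)
    )


def weighted_aic(
    net: BipartiteNetwork, model: str = "poisson", verbatim_sign: bool = False
) -> float:
    """Abundance-weighted AIC: 4kr + 2S - 2*sum(binary LL + abundance LL)."""
    ll = binary_ll_matrix(net, verbatim_sign).sum() + abundance_ll_total(net, model)
    return 4.0 * net.k * net.r + 2.0 * net.S - 2.0 * ll


@dataclass
class AicResult:
    """Likelihoods and AIC scores of the network at one threshold."""

    threshold_pct: int
    k: int
    ll_binary: float
    ll_abund: float
    aic_binary: float
    aic_weighted: float
    abundance_model: str


@dataclass
class AicCurve:
    """Per-threshold AIC results plus the argmin threshold.

    ``selection`` names the AIC column minimised ("aic_weighted" by default);
    equal scores resolve toward the lower threshold (fewer OTUs).
    """

    results: list[AicResult]
    selection: str = "aic_weighted"
    optimal_threshold: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.results:
            raise ValueError("empty AIC curve")
        scores = np.array([getattr(res, self.selection) for res in self.results])
        self.optimal_threshold = self.results[int(np.argmin(scores))].threshold_pct

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold_pct": [x.threshold_pct for x in self.results],
                "k": [x.k for x in self.results],
                "ll_binary": [x.ll_binary for x in self.results],
                "ll_abund": [x.ll_abund for x in self.results],
                "aic_binary": [x.aic_binary for x in self.results],
                "aic_weighted": [x.aic_weighted for x in self.results],
                "model": [x.abundance_model for x in self.results],
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def __getitem__(self, i: int) -> AicResult:
        return self.results[i]

    def __len__(self) -> int:
        return len(self.results)


def aic_curve(
    table: SequenceTypeTable,
    cluster_scan: ClusterScan,
    model: str = "poisson",
    weighted: bool = True,
    verbatim_sign: bool = False,
) -> AicCurve:
    """Score every partition of a threshold scan and locate the AIC minimum."""
    if model not in ABUNDANCE_MODELS:
        raise ValueError(f"unknown abundance model {model!r}")
    results = []
    for part in cluster_scan:
        net = build_network(table, part)
        ll_bin = float(binary_ll_matrix(net, verbatim_sign).sum())
        ll_ab = abundance_ll_total(net, model)
        results.append(
            AicResult(
                threshold_pct=part.threshold_pct,
                k=part.k,
                ll_binary=ll_bin,
                ll_abund=ll_ab,
                aic_binary=2.0 * net.k * net.r + 2.0 * net.S - 2.0 * ll_bin,
                aic_weighted=4.0 * net.k * net.r + 2.0 * net.S - 2.0 * (ll_bin + ll_ab),
                abundance_model=model,
            )
        )
    return AicCurve(results, selection="aic_weighted" if weighted else "aic_binary")


def select_optimal(curve: AicCurve) -> int:
    """The AIC-minimising similarity threshold (ties -> lower threshold)."""
    return curve.optimal_threshold
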
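"""Reading amplicon reads and building/serialising sequence-type abundance tables.

A *sequence type* is a distinct (exact-identity) DNA sequence obtained by
dereplicating reads; the abundance table records how many reads of each type
were observed in each plot (sample).  This table is the raw material for OTU
clustering and for the bipartite OTU-plot network likelihoods downstream.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")


class MappingError(KeyError):
    """A read could not be resolved to a plot label."""


@dataclass(frozen=True)
class SequenceRecord:
    """One amplicon read with its plot (sample) of origin."""

    read_id: str
    plot_label: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r}: empty sequence")


@dataclass
class ReadFastaResult:
    """Reads retained from a FASTA file plus a count of discarded ones.

    Reads containing ambiguous bases (anything outside A/C/G/T after
    uppercasing) are dropped, not corrected, and counted in
    ``n_dropped_ambiguous``.
    """

    records: list[SequenceRecord]
    n_dropped_ambiguous: int = 0

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def read_mapping(path: str | Path) -> dict[str, str]:
    """Read a two-column (read_id TAB plot) mapping file."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            mapping[parts[0]] = parts[1]
    return mapping


def read_fasta(
    path: str | Path,
    sample_map: Mapping[str, str] | str | Path | None = None,
    header_regex: str | None = None,
) -> ReadFastaResult:
    """Read demultiplexed FASTA reads and resolve each to a plot label.

    Parameters
    ----------
    path
        FASTA file (wrapped or single-line).
    sample_map
        Either an in-memory ``read_id -> plot`` mapping or the path of a
        two-column TSV.  Takes precedence over ``header_regex`` when both
        are given.
    header_regex
        Regex applied to the full FASTA header; group 1 (or the named group
        ``plot``) is the plot label.  Example: ``r"\\|([^|]+)$"`` takes the
        token after the last ``|``.

    Returns
    -------
    ReadFastaResult
        Retained records in file order (sequences uppercased) and the count
        of reads dropped for containing ambiguous bases.
    """
    if sample_map is None and header_regex is None:
        raise ValueError("provide sample_map and/or header_regex")
    if sample_map is not None and not isinstance(sample_map, Mapping):
        sample_map = read_mapping(sample_map)
    pattern = re.compile(header_regex) if header_regex else None

    records: list[SequenceRecord] = []
    n_dropped = 0
    n_total = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_total += 1
        seq = str(rec.seq).upper()
        if not set(seq) <= _VALID_BASES:
            n_dropped += 1
            continue
        plot = None
        if sample_map is not None:
            plot = sample_map.get(rec.id)
        if plot is None and pattern is not None:
            m = pattern.search(rec.description)
            if m:
                plot = m.groupdict().get("plot") or m.group(1)
        if plot is None:
            raise MappingError(f"read {rec.id!r} has no plot mapping")
        records.append(SequenceRecord(rec.id, plot, seq))
    if n_total == 0:
        logger.warning("FASTA file %s contains no reads", path)
    if n_dropped:
        logger.info("dropped %d read(s) with ambiguous bases", n_dropped)
    return ReadFastaResult(records, n_dropped)


@dataclass
class SequenceTypeTable:
    """Dereplicated sequence types with an S x r per-plot abundance matrix.

    Rows are ordered by decreasing total abundance, ties broken
    lexicographically by sequence, so tables are canonical and comparable.
    """

    sequences: list[str]
    plots: list[str]
    abundance: np.ndarray  # (S, r) non-negative ints

    def __post_init__(self) -> None:
        self.abundance = np.asarray(self.abundance, dtype=np.int64)
        S, r = self.abundance.shape
        if S != len(self.sequences) or r != len(self.plots):
            raise ValueError("abundance shape does not match sequences/plots")
        if (self.abundance < 0).any():
            raise ValueError("negative abundance")
        if len(set(self.sequences)) != S:
            raise ValueError("sequences must be pairwise distinct")
        if S and (self.abundance.sum(axis=1) < 1).any():
            raise ValueError("every sequence type needs total abundance >= 1")

    @property
    def n_types(self) -> int:
        return len(self.sequences)

    @property
    def n_plots(self) -> int:
        return len(self.plots)

    @property
    def total_reads(self) -> int:
        return int(self.abundance.sum())

    def totals(self) -> np.ndarray:
        """Per-type total abundance across plots."""
        return self.abundance.sum(axis=1)

    def expand(self) -> list[SequenceRecord]:
        """Inverse of dereplication: one record per counted read."""
        out = []
        i = 0
        for s, seq in enumerate(self.sequences):
            for q, plot in enumerate(self.plots):
                for _ in range(int(self.abundance[s, q])):
                    out.append(SequenceRecord(f"read{i:06d}", plot, seq))
                    i += 1
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SequenceTypeTable):
            return NotImplemented
        return (
            self.sequences == other.sequences
            and self.plots == other.plots
            and np.array_equal(self.abundance, other.abundance)
        )


def dereplicate(
    records: Iterable[SequenceRecord],
    min_length: int = 1,
    trim_to: int | None = None,
    plots: Sequence[str] | None = None,
) -> SequenceTypeTable:
    """Collapse exact-identical reads into sequence types with per-plot counts.

    Reads shorter than ``min_length`` (after optional trimming to ``trim_to``
    bases) are dropped.  Rows are sorted by decreasing total abundance, ties
    lexicographic by sequence.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to dereplicate")
    if plots is None:
        seen: dict[str, None] = {}
        for rec in records:
            seen.setdefault(rec.plot_label, None)
        plots = sorted(seen)
    plot_index = {p: i for i, p in enumerate(plots)}

    counts: dict[str, np.ndarray] = {}
    retained = 0
    for rec in records:
        seq = rec.sequence
        if trim_to is not None:
            seq = seq[:trim_to]
        if len(seq) < min_length:
            continue
        if rec.plot_label not in plot_index:
            raise MappingError(f"read {rec.read_id!r}: unknown plot {rec.plot_label!r}")
        row = counts.get(seq)
        if row is None:
            row = counts[seq] = np.zeros(len(plots), dtype=np.int64)
        row[plot_index[rec.plot_label]] += 1
        retained += 1
    if not counts:
        raise ValueError("all reads were filtered out")

    order = sorted(counts, key=lambda s: (-int(counts[s].sum()), s))
    table = SequenceTypeTable(
        sequences=order,
        plots=list(plots),
        abundance=np.stack([counts[s] for s in order]),
    )
    assert table.total_reads == retained
    return table


def write_table(table: SequenceTypeTable, path: str | Path) -> None:
    """Write a sequence-type table as TSV: header ``sequence<TAB>plot...``."""
    with open(path, "w") as fh:
        fh.write("sequence\t" + "\t".join(table.plots) + "\n")
        for seq, row in zip(table.sequences, table.abundance):
            fh.write(seq + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_table(path: str | Path) -> SequenceTypeTable:
    """Read a sequence-type table TSV written by :func:`write_table`."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        cols = header.split("\t")
        if len(cols) < 2 or cols[0] != "sequence":
            raise ValueError(f"{path}:1: malformed header {header!r}")
        plots = cols[1:]
        sequences: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(cols):
                raise ValueError(f"{path}:{lineno}: expected {len(cols)} columns")
            try:
                row = [int(v) for v in parts[1:]]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer abundance") from exc
            if any(v < 0 for v in row):
                raise ValueError(f"{path}:{lineno}: negative abundance")
            sequences.append(parts[0])
            rows.append(row)
    abundance = (
        np.asarray(rows, dtype=np.int64)
        if rows
        else np.zeros((0, len(plots)), dtype=np.int64)
    )
    return SequenceTypeTable(sequences, plots, abundance)
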
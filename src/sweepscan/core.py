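"""Core in-memory containers shared across the pipeline.

Coordinate convention: all positions held in memory are 1-based inclusive
(the VCF/GFF3 convention).  BED input/output is converted at the file
boundary in :mod:`sweepscan.formats`; nothing else ever shifts coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing diploid genotype in a dosage matrix.
MISSING: int = -1

MIGRATORY = "migratory"
FRESHWATER = "freshwater"

_VALID_BASES = frozenset("ACGT")


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(ValueError):
    """Well-formed input whose content violates a pipeline invariant."""


@dataclass
class IngestReport:
    """Bookkeeping from a reader: every data line is ingested or skipped."""

    n_data_lines: int = 0
    n_ingested: int = 0
    n_skipped: int = 0

    def consistent(self) -> bool:
        return self.n_ingested + self.n_skipped == self.n_data_lines


@dataclass
class GenotypeDataset:
    """Samples x biallelic SNP sites with alt-allele dosages.

    ``dosages[i, j]`` is the alt-allele count (0, 1 or 2) of sample ``i``
    at site ``j``, or :data:`MISSING`.  ``sites`` is a DataFrame with
    columns ``chrom, pos, ref, alt``; positions are 1-based and strictly
    increasing within each chromosome.
    """

    sample_ids: list[str]
    sites: pd.DataFrame
    dosages: np.ndarray
    ingest_report: IngestReport | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if self.dosages.shape != (len(self.sample_ids), len(self.sites)):
            raise ValidationError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.sites)} sites"
            )
        allowed = {0, 1, 2, MISSING}
        bad = set(np.unique(self.dosages)) - allowed
        if bad:
            raise ValidationError(f"invalid dosage values: {sorted(bad)}")
        if len(self.sites):
            for col in ("chrom", "pos", "ref", "alt"):
                if col not in self.sites.columns:
                    raise ValidationError(f"sites table missing column {col!r}")
            for _, grp in self.sites.groupby("chrom", sort=False):
                if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                    raise ValidationError("positions not strictly increasing within chrom")
            same = self.sites["ref"] == self.sites["alt"]
            if same.any():
                raise ValidationError("ref == alt at some site")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def take_sites(self, index: np.ndarray) -> "GenotypeDataset":
        """Subset to the given site indices (order preserved)."""
        return GenotypeDataset(
            sample_ids=list(self.sample_ids),
            sites=self.sites.iloc[index].reset_index(drop=True),
            dosages=self.dosages[:, index],
        )

    def sample_index(self, ids: list[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as exc:
            raise ValidationError(f"unknown sample id {exc.args[0]!r}") from None


@dataclass(frozen=True)
class Gene:
    """A gene locus; ``cds`` holds 1-based inclusive subintervals in
    5'->3' transcription order (descending coordinates on the minus strand)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    cds: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"gene {self.gene_id}: start > end")
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        for s, e in self.cds:
            if not (self.start <= s <= e <= self.end):
                raise ValidationError(f"gene {self.gene_id}: CDS ({s},{e}) outside gene body")
        ivals = sorted(self.cds)
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 <= e1:
                raise ValidationError(f"gene {self.gene_id}: overlapping CDS intervals")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)


@dataclass
class GeneAnnotation:
    genes: list[Gene]

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate gene ids")

    def by_chrom(self) -> dict[str, list[Gene]]:
        out: dict[str, list[Gene]] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g)
        for genes in out.values():
            genes.sort(key=lambda g: (g.start, g.end))
        return out


@dataclass
class SampleGrouping:
    """Assignment of every sample to the migratory or freshwater group."""

    assignment: dict[str, str]

    def __post_init__(self) -> None:
        bad = {v for v in self.assignment.values()} - {MIGRATORY, FRESHWATER}
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")

    def validate_against(self, ds: GenotypeDataset) -> None:
        missing = set(ds.sample_ids) - set(self.assignment)
        if missing:
            raise ValidationError(f"samples without group label: {sorted(missing)[:5]}")
        labels = {self.assignment[s] for s in ds.sample_ids}
        if labels != {MIGRATORY, FRESHWATER}:
            raise ValidationError("both groups must occur at least once")

    def members(self, label: str) -> list[str]:
        return [s for s, g in self.assignment.items() if g == label]


class PhyloTree:
    """Unrooted tree with labelled leaves and non-negative edge lengths.

    Nodes are integers; leaves carry string labels.  Edges are stored as an
    adjacency map ``node -> {neighbor: length}``.
    """

    def __init__(self) -> None:
        self._adj: dict[int, dict[int, float]] = {}
        self.leaf_labels: dict[int, str] = {}
        self._next_id = 0

    def add_node(self, label: str | None = None) -> int:
        node = self._next_id
        self._next_id += 1
        self._adj[node] = {}
        if label is not None:
            if label in self.leaf_labels.values():
                raise ValidationError(f"duplicate leaf label {label!r}")
            self.leaf_labels[node] = label
        return node

    def add_edge(self, u: int, v: int, length: float) -> None:
        if length < 0:
            raise ValidationError("negative edge length")
        self._adj[u][v] = float(length)
        self._adj[v][u] = float(length)

    @property
    def nodes(self) -> list[int]:
        return list(self._adj)

    def neighbors(self, node: int) -> dict[int, float]:
        return self._adj[node]

    def edges(self) -> list[tuple[int, int, float]]:
        seen = set()
        out = []
        for u, nbrs in self._adj.items():
            for v, ln in nbrs.items():
                key = (min(u, v), max(u, v))
                if key not in seen:
                    seen.add(key)
                    out.append((key[0], key[1], ln))
        return out

    def is_leaf(self, node: int) -> bool:
        return node in self.leaf_labels

    def leaves(self) -> list[int]:
        return sorted(self.leaf_labels)

    def leaves_beyond(self, start: int, blocked: int) -> set[int]:
        """Leaf nodes reachable from ``start`` without crossing ``blocked``."""
        stack, seen, out = [start], {blocked, start}, set()
        while stack:
            node = stack.pop()
            if self.is_leaf(node):
                out.add(node)
            for nbr in self._adj[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        return out

    def path_distances(self) -> pd.DataFrame:
        """All-pairs leaf-to-leaf path lengths (labels as index/columns)."""
        leaves = self.leaves()
        labels = [self.leaf_labels[v] for v in leaves]
        n = len(leaves)
        mat = np.zeros((n, n))
        for i, src in enumerate(leaves):
            dist = {src: 0.0}
            stack = [src]
            while stack:
                node = stack.pop()
                for nbr, ln in self._adj[node].items():
                    if nbr not in dist:
                        dist[nbr] = dist[node] + ln
                        stack.append(nbr)
            for j, dst in enumerate(leaves):
                mat[i, j] = dist[dst]
        return pd.DataFrame(mat, index=labels, columns=labels)
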
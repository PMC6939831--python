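"""Population grouping from genotypes: IBS distances, neighbor joining,
and a two-group split at the longest internal edge.

The pairwise distance is 1 - IBS with per-pair renormalization ("flat
missing"): for each sample pair only sites where both genotypes are
observed contribute, with per-site distance |dosage_i - dosage_j| / 2,
and the mean is taken over that pair's own non-missing count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, FRESHWATER, MIGRATORY, GenotypeDataset, PhyloTree, SampleGrouping, ValidationError

log = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise ValidationError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValidationError("distance matrix diagonal not zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


def ibs_distance(ds: GenotypeDataset) -> DistanceMatrix:
    """1-IBS genetic distance between all sample pairs.

    Raises if any pair shares zero non-missing sites, since its distance
    would be undefined.
    """
    if ds.n_samples < 2:
        raise ValidationError("need at least 2 samples")
    g = ds.dosages.astype(np.int16)
    obs = (g != MISSING)
    gz = np.where(obs, g, 0)
    n = ds.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        # |g_i - g_j| over sites observed in both, normalized per pair
        both = obs[i] & obs[i:]
        diff = np.abs(gz[i] - gz[i:]) * both
        shared = both.sum(axis=1)
        zero = np.flatnonzero(shared == 0)
        if zero.size:
            j = int(zero[0]) + i
            raise ValidationError(
                f"samples {ds.sample_ids[i]!r} and {ds.sample_ids[j]!r} "
                "share no non-missing sites")
        d[i, i:] = diff.sum(axis=1) / (2.0 * shared)
    d = d + d.T
    return DistanceMatrix(labels=list(ds.sample_ids), d=d)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Classic Saitou-Nei neighbor joining.

    At each step the pair minimizing Q(i,j) = (n-2) d(i,j) - r_i - r_j is
    joined; ties are broken by the lowest active-index pair.  Negative
    branch lengths are clamped to zero with the deficit logged.  The last
    three nodes are joined to a single degree-3 hub.
    """
    n0 = len(dm.labels)
    if n0 < 3:
        raise ValidationError("neighbor joining needs at least 3 taxa")
    tree = PhyloTree()
    active_nodes = [tree.add_node(label) for label in dm.labels]
    d = dm.d.copy()
    clamp_deficit = 0.0

    while len(active_nodes) > 3:
        m = len(active_nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie-break: first argmin in row-major order wins
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj, clamp_deficit = _clamp(li, lj, clamp_deficit)
        new = tree.add_node()
        tree.add_edge(active_nodes[i], new, li)
        tree.add_edge(active_nodes[j], new, lj)
        dnew = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.pad(d[np.ix_(keep, keep)], ((0, 1), (0, 1)))
        d[-1, :-1] = d[:-1, -1] = dnew[keep]
        active_nodes = [active_nodes[k] for k in keep] + [new]

    # final 3-node join: closed-form star lengths
    a, b, c = active_nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    hub = tree.add_node()
    for node, ln in ((a, la), (b, lb), (c, lc)):
        if ln < 0:
            clamp_deficit += -ln
            ln = 0.0
        tree.add_edge(node, hub, ln)
    if clamp_deficit > 0:
        log.info("neighbor_joining: clamped %.3g of negative branch length",
                 clamp_deficit)
    return tree


def _clamp(li: float, lj: float, deficit: float) -> tuple[float, float, float]:
    if li < 0:
        deficit += -li
        li = 0.0
    if lj < 0:
        deficit += -lj
        lj = 0.0
    return li, lj, deficit


def split_by_longest_edge(tree: PhyloTree) -> tuple[list[str], list[str]]:
    """Bipartition the leaves by removing the longest internal edge.

    Ties go to the edge whose smaller side has more leaves, then to the
    lexicographically smallest leaf-label tuple of the smaller side.
    Returns (smaller side, larger side), each sorted.
    """
    if len(tree.leaves()) < 4:
        raise ValidationError("need at least 4 leaves to split")
    internal = [(u, v, ln) for u, v, ln in tree.edges()
                if not tree.is_leaf(u) and not tree.is_leaf(v)]
    if not internal:
        raise ValidationError("tree has no internal edge (star topology)")

    best = None
    for u, v, ln in internal:
        side_u = sorted(tree.leaf_labels[x] for x in tree.leaves_beyond(u, v))
        side_v = sorted(tree.leaf_labels[x] for x in tree.leaves_beyond(v, u))
        small, big = sorted([side_u, side_v], key=lambda s: (len(s), s))
        # maximize length, then smaller-side size, then lexicographic small side
        cand = (ln, len(small), small, big)
        if best is None or _better(cand, best):
            best = cand
    _, _, small, big = best
    return small, big


def _better(cand, best) -> bool:
    if cand[0] != best[0]:
        return cand[0] > best[0]
    if cand[1] != best[1]:
        return cand[1] > best[1]
    return cand[2] < best[2]


def infer_grouping(tree: PhyloTree) -> SampleGrouping:
    """Two-group call from the tree: the smaller side of the longest
    internal edge is labelled freshwater (the minority phenotype), the
    larger side migratory.  A user-supplied grouping always overrides
    this downstream."""
    small, big = split_by_longest_edge(tree)
    assignment = {s: FRESHWATER for s in small}
    assignment.update({s: MIGRATORY for s in big})
    return SampleGrouping(assignment=assignment)
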
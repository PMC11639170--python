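"""Tree-set introgression statistics: Dtree and the MMS17 dMRCA statistic.

Both statistics summarize a set of local trees for a species trio
(P1, P2, P3) with outgroup P4.  Dtree compares the counts of the two
discordant rooted trio topologies,

    Dtree = (C_P2,P3 - C_P1,P3) / (C_P2,P3 + C_P1,P3),

with a one-sided exact binomial test of C_P2,P3 > C_P1,P3 (this is the
constrained form that tests explicitly for P2-P3 introgression; the
unconstrained form comparing the second- and third-most frequent
topologies is available as an option).  Trees whose trio internal
branch is shorter than a threshold (default 0.001 substitutions/site)
are considered uninformative and excluded from the counts.

The MMS17 statistic takes ultrametric, time-calibrated local trees and
compares the mean MRCA ages of the pairs P1-P2, P1-P3 and P2-P3 over
all trees; dMRCA is the difference between the two largest pair means.
Elevated dMRCA suggests introgression.  No formal test is attached; the
identities of the two oldest pairs are reported so that pathological
orderings (e.g. P1-P2 among the two oldest) can be recognized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

ROLES = ("P1", "P2", "P3", "P4")
TOPOLOGIES = ("P1P2", "P1P3", "P2P3")
_PAIR_OF_TOPOLOGY = {"P1P2": ("P1", "P2"), "P1P3": ("P1", "P3"), "P2P3": ("P2", "P3")}


@dataclass
class TreeRecord:
    """Summary of one 4-taxon tree: trio topology and key path lengths."""

    topology: str  # cherry pair among the trio: "P1P2", "P1P3" or "P2P3"
    internal_length: float  # trio internal branch (middle edge) length
    pair_distance: dict[str, float]  # patristic distances d(P1,P2), d(P1,P3), d(P2,P3)
    tip_depth_spread: float = 0.0  # max - min root-to-tip length (clock check)
    root_height: float = 0.0
    filtered: bool = False


@dataclass
class TreeSet:
    """Parsed and summarized local trees."""

    records: list[TreeRecord]
    n_skipped: int = 0
    filter_threshold: float = 0.001

    @property
    def n_trees(self) -> int:
        return len(self.records)

    @property
    def n_filtered(self) -> int:
        return sum(r.filtered for r in self.records)

    @property
    def n_used(self) -> int:
        return self.n_trees - self.n_filtered


@dataclass
class DtreeResult:
    counts: dict[str, int]  # per topology, among unfiltered trees
    dtree: float | None
    p: float
    n_used: int
    n_filtered: int
    constrained: bool = True


@dataclass
class MMS17Result:
    mean_mrca_age: dict[str, float]  # per trio pair
    dmrca: float
    oldest_pairs: tuple[str, str]
    n_trees: int


def _summarize_tree(tree: dendropy.Tree, label_to_role: dict[str, str],
                    filter_threshold: float) -> TreeRecord:
    """Reduce a 4-taxon tree to topology + distances.

    Works on rooted and unrooted newick alike: the trio topology is the
    quartet split (the cherry pair not containing P4), and the internal
    branch length is recovered from patristic distances, which is exact
    on additive trees and independent of root placement.
    """
    role_leaf: dict[str, dendropy.Node] = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon else None
        role = label_to_role.get(label)
        if role is None:
            raise ValueError(f"unmapped taxon {label!r}")
        if role in role_leaf:
            raise ValueError(f"duplicate taxon for role {role}")
        role_leaf[role] = leaf
    missing = [r for r in ROLES if r not in role_leaf]
    if missing:
        raise ValueError(f"missing taxa for roles {missing}")

    # Root-to-leaf path lengths give patristic distances via the MRCA.
    depth: dict[str, float] = {}
    path_nodes: dict[str, list[dendropy.Node]] = {}
    for role, leaf in role_leaf.items():
        d = 0.0
        nodes = []
        node = leaf
        while node is not None:
            nodes.append(node)
            if node.edge.length is not None and node.parent_node is not None:
                d += node.edge.length
            node = node.parent_node
        depth[role] = d
        path_nodes[role] = nodes

    def dist(a: str, b: str) -> float:
        ancestors_a = {id(n): i for i, n in enumerate(path_nodes[a])}
        d_b = 0.0
        for node in path_nodes[b]:
            if id(node) in ancestors_a:
                d_a = sum(
                    n.edge.length or 0.0
                    for n in path_nodes[a][: ancestors_a[id(node)]]
                )
                return d_a + d_b
            d_b += node.edge.length or 0.0
        raise ValueError("disconnected leaves")

    pd = {f"{a}{b}": dist(a, b) for a, b in (("P1", "P2"), ("P1", "P3"), ("P2", "P3"))}
    d14, d24, d34 = dist("P1", "P4"), dist("P2", "P4"), dist("P3", "P4")

    # Quartet split from the structure: an edge with exactly two of the
    # four leaves below it defines the middle split.
    cherry = None
    leaf_ids = {id(role_leaf[r]): r for r in ROLES}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(leaf_ids[id(l)] for l in node.leaf_iter() if id(l) in leaf_ids)
        if len(below) == 2:
            # The complement of a side containing P4 is the trio cherry.
            cherry = below if "P4" not in below else frozenset(ROLES) - below
            break
    if cherry is None:
        raise ValueError("tree has no resolved quartet split")
    topology = next(t for t in TOPOLOGIES if frozenset(_PAIR_OF_TOPOLOGY[t]) == cherry)

    y, z = sorted(cherry)
    (x,) = {"P1", "P2", "P3"} - cherry
    dx = {"P1": d14, "P2": d24, "P3": d34}

    def trio_dist(a: str, b: str) -> float:
        key = "".join(sorted((a, b)))
        return pd[key]

    internal = 0.5 * (trio_dist(y, x) + dx[z] - trio_dist(y, z) - dx[x])
    depths = list(depth.values())
    return TreeRecord(
        topology=topology,
        internal_length=internal,
        pair_distance=pd,
        tip_depth_spread=max(depths) - min(depths),
        root_height=max(depths),
        filtered=internal < filter_threshold,
    )


def read_tree_set(
    source,
    taxon_map: dict[str, str] | None = None,
    filter_threshold: float = 0.001,
) -> TreeSet:
    """Parse a multi-tree newick file (one tree per line) into a TreeSet.

    Parameters
    ----------
    source
        Path, open text stream, or newick string containing the trees.
    taxon_map
        Mapping from taxon labels in the file to roles P1..P4.  Defaults
        to the identity mapping on labels "P1".."P4".
    filter_threshold
        Trees whose trio internal branch is shorter than this are
        flagged as uninformative and excluded from topology counts.
    """
    if taxon_map is None:
        taxon_map = {r: r for r in ROLES}
    if hasattr(source, "read"):
        text = source.read()
    else:
        source = str(source)
        if source.lstrip().startswith("("):
            text = source
        else:
            with open(source) as fh:
                text = fh.read()

    records: list[TreeRecord] = []
    n_skipped = 0
    for line_no, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            tree = dendropy.Tree.get(data=line, schema="newick",
                                     suppress_internal_node_taxa=True)
            records.append(_summarize_tree(tree, taxon_map, filter_threshold))
        except Exception as exc:
            n_skipped += 1
            logger.warning("skipping tree on line %d: %s", line_no, exc)
    if n_skipped:
        logger.warning("skipped %d unusable trees out of %d", n_skipped,
                       n_skipped + len(records))
    return TreeSet(records, n_skipped=n_skipped, filter_threshold=filter_threshold)


def dtree_test(trees: TreeSet, constrained: bool = True) -> DtreeResult:
    """Topology counts, Dtree, and one-sided exact binomial p-value.

    In the constrained form the test asks whether trees pairing P2 with
    P3 outnumber trees pairing P1 with P3 (introgression between P2 and
    P3).  In the unconstrained form the second- and third-most frequent
    topologies take those places.
    """
    counts = {t: 0 for t in TOPOLOGIES}
    for rec in trees.records:
        if not rec.filtered:
            counts[rec.topology] += 1
    if constrained:
        c_hi, c_lo = counts["P2P3"], counts["P1P3"]
    else:
        ranked = sorted(counts.values(), reverse=True)
        c_hi, c_lo = ranked[1], ranked[2]
    n = c_hi + c_lo
    if n == 0:
        return DtreeResult(counts, None, 1.0, trees.n_used, trees.n_filtered, constrained)
    dtree = (c_hi - c_lo) / n
    p = stats.binomtest(c_hi, n, 0.5, alternative="greater").pvalue
    return DtreeResult(counts, dtree, float(p), trees.n_used, trees.n_filtered, constrained)


def mms17_dmrca(trees: TreeSet, ultrametric_rtol: float = 1e-6) -> MMS17Result:
    """Mean pairwise MRCA ages and their dMRCA over a set of time trees.

    Pair MRCA age is half the patristic distance between the pair,
    which on an ultrametric tree equals the MRCA node age and otherwise
    equals the mean of the two tip-to-MRCA path lengths.  No internal
    branch filter is applied.  dMRCA is the absolute difference between
    the two largest pair means; the identities of those two pairs are
    reported so that pathological orderings can be recognized.
    """
    if not trees.records:
        raise ValueError("empty tree set")
    ages = {key: [] for key in ("P1P2", "P1P3", "P2P3")}
    n_nonclock = 0
    for rec in trees.records:
        if rec.root_height > 0 and rec.tip_depth_spread / rec.root_height > ultrametric_rtol:
            n_nonclock += 1
        # Half the patristic distance: the MRCA node age on a clock
        # tree, the mean tip-to-MRCA path length otherwise.
        for key, val in rec.pair_distance.items():
            ages[key].append(val / 2.0)
    if n_nonclock:
        logger.warning("%d of %d trees exceed the ultrametricity tolerance; "
                       "pair ages taken as half patristic distances",
                       n_nonclock, len(trees.records))
    means = {k: float(np.mean(v)) for k, v in ages.items()}
    ranked = sorted(means, key=means.get, reverse=True)
    dmrca = abs(means[ranked[0]] - means[ranked[1]])
    return MMS17Result(means, dmrca, (ranked[0], ranked[1]), trees.n_trees)
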
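"""Duplication/speciation labeling and orthology from rooted gene trees.

The species-overlap rule labels an internal gene-tree node a duplication
iff the species sets of (any pair of) its child subtrees intersect, and a
speciation otherwise.  It is parameter-free and needs no species-tree
reconciliation; under a duplication/loss-only generative model every
overlap-called duplication is a true duplication (speciation descendants
carry disjoint species sets), while losses can hide a duplication's
overlap, so recall is 1 only when nothing is lost.

From the labels: a leaf pair is orthologous iff its LCA is a speciation
(paralogous iff a duplication); the one-to-one / one-to-many /
many-to-many relation type counts the same-species co-orthologs on each
side of the LCA.  A duplication node splits its subtree into two paralog
clades (e.g. the animal-like MCU clade vs the fungal-specific MCUP clade),
whose per-species presence feeds the phylogenetic profiling stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import dendropy

SPECIES_GENE_SEP = "|"

SPECIATION = "speciation"
DUPLICATION = "duplication"


@dataclass(frozen=True)
class OrthologClade:
    subfamily: str
    genes: frozenset
    species: frozenset
    defining_node: object = None


def leaf_species(leaf: dendropy.Node, sep: str = SPECIES_GENE_SEP) -> str:
    if getattr(leaf, "species", None):
        return leaf.species
    label = leaf.taxon.label
    species, found, _ = label.partition(sep)
    if not found:
        raise ValueError(f"leaf label {label!r} lacks the {sep!r} separator")
    return species


def read_gene_tree(source: str, sep: str = SPECIES_GENE_SEP) -> dendropy.Tree:
    """Parse a rooted newick gene tree with 'species|gene' leaf labels."""
    tree = dendropy.Tree.get(data=source, schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = True
    for leaf in tree.leaf_node_iter():
        leaf.species = leaf_species(leaf, sep)
    return tree


def _require_rooted(tree: dendropy.Tree) -> None:
    root_children = tree.seed_node.child_nodes()
    if len(root_children) > 2:
        raise ValueError("tree appears unrooted (basal multifurcation); "
                         "root it first with root_tree()")
    if len(list(tree.leaf_node_iter())) < 2:
        raise ValueError("gene tree needs >= 2 leaves")


def annotate_events(tree: dendropy.Tree, sep: str = SPECIES_GENE_SEP
                    ) -> dict[dendropy.Node, str]:
    """Species-overlap event labels for every internal node.

    Multifurcations are treated pairwise: any intersecting pair of child
    species sets makes the node a duplication.  Labels are also stored on
    the nodes as ``node.event``.
    """
    _require_rooted(tree)
    labels: dict[dendropy.Node, str] = {}
    species_below: dict[dendropy.Node, frozenset] = {}
    for node in tree.postorder_node_iter():
        kids = node.child_nodes()
        if not kids:
            species_below[node] = frozenset([leaf_species(node, sep)])
            continue
        sets = [species_below[k] for k in kids]
        overlap = any(a & b for a, b in combinations(sets, 2))
        labels[node] = DUPLICATION if overlap else SPECIATION
        node.event = labels[node]
        species_below[node] = frozenset().union(*sets)
    return labels


def events_by_leafset(tree: dendropy.Tree, labels: dict[dendropy.Node, str]
                      ) -> dict[frozenset, str]:
    """Serializable view of the labels, keyed by each node's leaf-label set."""
    return {frozenset(l.taxon.label for l in node.leaf_iter()): event
            for node, event in labels.items()}


def _leaf_distances(tree: dendropy.Tree) -> dict:
    """Patristic distances between all leaf pairs (missing lengths = 0)."""
    dist: dict[tuple, float] = {}
    for node in tree.postorder_node_iter():
        kids = node.child_nodes()
        if not kids:
            node._below = {node: 0.0}
            continue
        below = {}
        for k in kids:
            el = k.edge.length or 0.0
            for leaf, d in k._below.items():
                below[leaf] = d + el
        for a, b in combinations(kids, 2):
            ela, elb = a.edge.length or 0.0, b.edge.length or 0.0
            for la, da in a._below.items():
                for lb, db in b._below.items():
                    dist[(la, lb)] = dist[(lb, la)] = da + ela + db + elb
        node._below = below
    return dist


def root_tree(tree: dendropy.Tree, method: str = "midpoint",
              outgroup_leaves=None) -> dendropy.Tree:
    """Deterministically rooted copy of the tree.

    midpoint: root at the center of the longest leaf-to-leaf path (ties
    broken by the lexicographically smallest leaf-name pair).
    outgroup: root on the edge above the MRCA of the named leaves; if the
    MRCA is already a child of the root, the tree is returned unchanged.
    """
    tree = tree.clone(depth=1)
    tree.is_rooted = True
    if method == "outgroup":
        if not outgroup_leaves:
            raise ValueError("outgroup rooting needs a non-empty leaf set")
        wanted = set(outgroup_leaves)
        labels = {l.taxon.label for l in tree.leaf_node_iter()}
        missing = wanted - labels
        if missing:
            raise ValueError(f"outgroup leaves not in tree: {sorted(missing)}")
        mrca = tree.mrca(taxon_labels=sorted(wanted))
        if mrca is tree.seed_node:
            raise ValueError("outgroup spans the whole tree; cannot root on it")
        if mrca.parent_node is tree.seed_node and len(tree.seed_node.child_nodes()) == 2:
            return tree
        el = mrca.edge.length
        half = None if el is None else el / 2.0
        tree.reroot_at_edge(mrca.edge, length1=half, length2=half,
                            update_bipartitions=False)
        tree.suppress_unifurcations()
        return tree
    if method != "midpoint":
        raise ValueError(f"unknown rooting method {method!r}")
    dist = _leaf_distances(tree)
    if not dist:
        return tree
    def pair_key(item):
        (a, b), d = item
        names = sorted([a.taxon.label, b.taxon.label])
        return (-d, names[0], names[1])
    (a, b), dmax = min(dist.items(), key=pair_key)
    if a.taxon.label > b.taxon.label:
        a, b = b, a
    # walk from leaf a towards b; the midpoint lies dmax/2 from a
    pdm_path = _path_between(tree, a, b)
    half = dmax / 2.0
    acc = 0.0
    for node, edge_len, towards_root in pdm_path:
        if acc + edge_len >= half - 1e-12:
            offset = half - acc  # distance from the a-side end of this edge
            if towards_root:
                length1, length2 = edge_len - offset, offset
            else:
                length1, length2 = offset, edge_len - offset
            tree.reroot_at_edge(node.edge, length1=length1, length2=length2,
                                update_bipartitions=False)
            tree.suppress_unifurcations()
            return tree
        acc += edge_len
    raise AssertionError("midpoint not found on the maximal path")


def _path_between(tree, a, b):
    """Edges along the path a -> b as (child_node, edge_length, towards_root)."""
    anc_a, node = [], a
    while node is not None:
        anc_a.append(node)
        node = node.parent_node
    anc_b, node = [], b
    while node is not None:
        anc_b.append(node)
        node = node.parent_node
    set_a = set(anc_a)
    lca = next(n for n in anc_b if n in set_a)
    up = [(n, n.edge.length or 0.0, True) for n in anc_a[:anc_a.index(lca)]]
    down = [(n, n.edge.length or 0.0, False) for n in anc_b[:anc_b.index(lca)]]
    return up + list(reversed(down))


def split_paralog_clades(tree: dendropy.Tree, labels: dict,
                         duplication_node: dendropy.Node,
                         subfamily_tags: tuple[str, str] = ("A", "B"),
                         sep: str = SPECIES_GENE_SEP
                         ) -> tuple[OrthologClade, OrthologClade]:
    """Split the subtree under a duplication into its two paralog clades.

    The children subtrees (e.g. animal-like MCU vs fungal-specific MCUP)
    are leaf-disjoint and jointly cover the duplication's subtree; species
    retained in both (the chytrid-like pattern) appear in both clades.
    """
    if labels.get(duplication_node) != DUPLICATION:
        raise ValueError("node is not labeled as a duplication")
    kids = duplication_node.child_nodes()
    if len(kids) != 2:
        raise ValueError("paralog splitting expects a bifurcating duplication")
    clades = []
    for tag, kid in zip(subfamily_tags, kids):
        leaves = list(kid.leaf_iter())
        clades.append(OrthologClade(
            subfamily=tag,
            genes=frozenset(l.taxon.label for l in leaves),
            species=frozenset(leaf_species(l, sep) for l in leaves),
            defining_node=duplication_node))
    return clades[0], clades[1]


def ortholog_pairs(tree: dendropy.Tree, labels: dict,
                   sep: str = SPECIES_GENE_SEP) -> set[tuple[str, str, str]]:
    """All ortholog pairs with their relation type.

    A pair is orthologous iff its LCA is a speciation.  For a pair (a, b)
    meeting at node S through child subtrees X (containing a) and Y, the
    co-ortholog counts are the number of genes of a's species in X and of
    b's species in Y; (1,1) -> one-to-one, one side > 1 -> one-to-many,
    both -> many-to-many.  Output is symmetric, pairs ordered (min, max).
    """
    pairs: set[tuple[str, str, str]] = set()
    per_node: dict[dendropy.Node, list] = {}
    for node in tree.postorder_node_iter():
        kids = node.child_nodes()
        if not kids:
            per_node[node] = [(node.taxon.label, leaf_species(node, sep))]
            continue
        sides = [per_node[k] for k in kids]
        if labels[node] == SPECIATION:
            for side_x, side_y in combinations(sides, 2):
                species_count_x: dict[str, int] = {}
                species_count_y: dict[str, int] = {}
                for _, sp in side_x:
                    species_count_x[sp] = species_count_x.get(sp, 0) + 1
                for _, sp in side_y:
                    species_count_y[sp] = species_count_y.get(sp, 0) + 1
                for ga, sa in side_x:
                    for gb, sb in side_y:
                        na, nb = species_count_x[sa], species_count_y[sb]
                        if na == 1 and nb == 1:
                            rel = "one-to-one"
                        elif na > 1 and nb > 1:
                            rel = "many-to-many"
                        else:
                            rel = "one-to-many"
                        x, y = sorted([ga, gb])
                        pairs.add((x, y, rel))
        per_node[node] = [g for side in sides for g in side]
    return pairs


def paralog_pairs(tree: dendropy.Tree, labels: dict) -> set[tuple[str, str]]:
    """Leaf pairs whose LCA is a duplication (complement of ortholog_pairs)."""
    pairs: set[tuple[str, str]] = set()
    per_node: dict[dendropy.Node, list] = {}
    for node in tree.postorder_node_iter():
        kids = node.child_nodes()
        if not kids:
            per_node[node] = [node.taxon.label]
            continue
        sides = [per_node[k] for k in kids]
        if labels[node] == DUPLICATION:
            for sx, sy in combinations(sides, 2):
                for ga in sx:
                    for gb in sy:
                        pairs.add(tuple(sorted([ga, gb])))
        per_node[node] = [g for side in sides for g in side]
    return pairs


def clade_presence(clades, species_universe) -> dict[str, dict[str, int]]:
    """presence[species][subfamily] = 1 iff the species has a leaf in the clade."""
    universe = sorted(species_universe)
    for clade in clades:
        stray = clade.species - set(universe)
        if stray:
            raise ValueError(f"clade species outside the universe: {sorted(stray)}")
    return {sp: {clade.subfamily: int(sp in clade.species) for clade in clades}
            for sp in universe}
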
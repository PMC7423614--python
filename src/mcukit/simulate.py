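"""Synthetic data with ground truth for every pipeline stage.

Generates (i) ultrametric species trees from a coalescent-style sampler,
(ii) gene families evolving along the species tree under a continuous-time
birth--death process of duplication and loss, with true per-node event
labels, (iii) proteomes in which each surviving gene carries one diverged
copy of its family's domain template among random decoy proteins, and
(iv) aequorin luminescence traces forward-simulated from a known Ca2+
series with finite-reporter consumption and optional Poisson counting
noise.  Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .alphabet import mutate, random_protein
from .aequorin import CalciumTrace, CalibrationConstants, LuminescenceTrace

SPECIES_GENE_SEP = "|"


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for the gene-family / proteome generators."""

    n_species: int = 8
    dup_rate: float = 0.3
    loss_rate: float = 0.2
    seed: int = 0
    domain_divergence: float = 0.1
    decoys_per_proteome: int = 20
    flank_range: tuple[int, int] = (15, 60)
    decoy_length_range: tuple[int, int] = (80, 200)

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.dup_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.domain_divergence < 1.0:
            raise ValueError("domain_divergence must be in [0, 1)")
        if self.decoys_per_proteome < 0:
            raise ValueError("decoys_per_proteome must be >= 0")


@dataclass
class TrueHistory:
    """Ground truth emitted by the generators.

    events maps the frozen leaf-label set of each surviving internal gene-tree
    node to its true event ("speciation" | "duplication"); presence maps
    species id to True iff >= 1 gene copy survived there; domains maps
    sequence id to a list of (start, end, template_id) 0-based half-open
    planted-domain coordinates; true_ca holds the molar Ca2+ series behind a
    simulated luminescence trace.
    """

    events: dict[frozenset, str] = field(default_factory=dict)
    presence: dict[str, bool] = field(default_factory=dict)
    domains: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)
    true_ca: CalciumTrace | None = None


def simulate_species_tree(n_species: int, seed: int) -> dendropy.Tree:
    """Coalescent-style ultrametric rooted binary species tree.

    Leaves are named ``s1..sN``; all root-to-leaf path lengths are equal by
    construction.  Deterministic given the seed.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    nodes = []
    for i in range(n_species):
        taxon = dendropy.Taxon(label=f"s{i + 1}")
        taxa.add_taxon(taxon)
        node = dendropy.Node(taxon=taxon)
        node.height = 0.0
        nodes.append(node)
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = nodes[i], nodes[j]
        parent = dendropy.Node()
        parent.height = t
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = t - a.height
        b.edge.length = t - b.height
        nodes = [n for m, n in enumerate(nodes) if m not in (i, j)]
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=nodes[0])
    tree.is_rooted = True
    return tree


def _species_depths(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    depths = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    return depths


class _GeneCounter:
    def __init__(self) -> None:
        self.k = 0

    def __call__(self) -> str:
        self.k += 1
        return f"g{self.k}"


def simulate_gene_family(tree: dendropy.Tree, cfg: SimulationConfig
                         ) -> tuple[dendropy.Tree | None, TrueHistory]:
    """Birth--death gene family along the species tree.

    A single gene enters at the species-tree root; along each branch it
    duplicates (rate ``dup_rate``) or dies (rate ``loss_rate``) in continuous
    time with exponential waiting times; surviving lineages speciate at
    species-tree nodes.  The returned gene tree contains only surviving
    leaves, labelled ``species|gene``; internal nodes carry a ``true_event``
    attribute, mirrored in the TrueHistory keyed by leaf-label sets.  If
    every lineage dies the family is absent: ``(None, history)`` with all
    presence False.
    """
    rng = np.random.default_rng(cfg.seed)
    depths = _species_depths(tree)
    next_gene = _GeneCounter()
    total = cfg.dup_rate + cfg.loss_rate

    def evolve(sp_node: dendropy.Node, t_elapsed: float):
        """Evolve one lineage from `t_elapsed` into sp_node's branch."""
        length = 0.0 if sp_node.parent_node is None else (sp_node.edge.length or 0.0)
        t = t_elapsed
        while total > 0:
            wait = rng.exponential(1.0 / total)
            if t + wait >= length:
                break
            t += wait
            if rng.random() < cfg.dup_rate / total:
                t_abs = depths.get(sp_node, 0.0) - (length - t)
                left = evolve(sp_node, t)
                right = evolve(sp_node, t)
                kids = [c for c in (left, right) if c is not None]
                if not kids:
                    return None
                if len(kids) == 1:
                    return kids[0]
                node = dendropy.Node()
                node.true_event = "duplication"
                node.t_abs = t_abs
                for c in kids:
                    node.add_child(c)
                return node
            return None  # loss
        # reached the end of the branch
        if sp_node.is_leaf():
            leaf = dendropy.Node()
            leaf.species = sp_node.taxon.label
            leaf.gene = next_gene()
            leaf.t_abs = depths[sp_node]
            return leaf
        kids = [evolve(child, 0.0) for child in sp_node.child_nodes()]
        kids = [c for c in kids if c is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        node = dendropy.Node()
        node.true_event = "speciation"
        node.t_abs = depths[sp_node]
        for c in kids:
            node.add_child(c)
        return node

    root = evolve(tree.seed_node, 0.0)
    history = TrueHistory(
        presence={leaf.taxon.label: False for leaf in tree.leaf_node_iter()})
    if root is None:
        return None, history

    taxa = dendropy.TaxonNamespace()
    for node in _postorder(root):
        if not node.child_nodes():
            label = f"{node.species}{SPECIES_GENE_SEP}{node.gene}"
            node.taxon = dendropy.Taxon(label=label)
            taxa.add_taxon(node.taxon)
            history.presence[node.species] = True
    gene_tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    gene_tree.is_rooted = True
    for node in gene_tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = max(node.t_abs - node.parent_node.t_abs, 0.0)
        if node.child_nodes():
            leafset = frozenset(l.taxon.label for l in node.leaf_iter())
            history.events[leafset] = node.true_event
    return gene_tree, history


def _postorder(root: dendropy.Node):
    stack, out = [root], []
    while stack:
        node = stack.pop()
        out.append(node)
        stack.extend(node.child_nodes())
    return reversed(out)


def gene_leaves(gene_tree: dendropy.Tree) -> list[tuple[str, str]]:
    """(species, sequence-id) pairs for every surviving gene."""
    out = []
    for leaf in gene_tree.leaf_node_iter():
        species, _, _gene = leaf.taxon.label.partition(SPECIES_GENE_SEP)
        out.append((species, leaf.taxon.label))
    return out


def plant_domains(families, templates, cfg: SimulationConfig,
                  species_universe=None
                  ) -> tuple[dict[str, dict[str, str]], TrueHistory]:
    """Build per-species proteomes with planted, diverged domain copies.

    ``families`` maps family name -> gene tree (or ``None`` for an absent
    family); ``templates`` maps family name -> consensus domain sequence.
    A single gene tree with a list of templates is accepted as shorthand
    (family ``fam0``, first template).  Each surviving gene yields one
    protein: random flanks around one mutated template copy (per-position
    substitution probability ``cfg.domain_divergence``), plus
    ``cfg.decoys_per_proteome`` unrelated background sequences per species.
    Planted coordinates are recorded as 0-based half-open intervals.
    """
    if isinstance(families, dendropy.Tree) or families is None:
        template = templates[0] if isinstance(templates, (list, tuple)) else templates
        families = {"fam0": families}
        templates = {"fam0": template}
    if not templates:
        raise ValueError("templates must be non-empty")
    rng = np.random.default_rng(cfg.seed + 1)
    species = set(species_universe or [])
    for tree in families.values():
        if tree is not None:
            species.update(sp for sp, _ in gene_leaves(tree))
    proteomes: dict[str, dict[str, str]] = {sp: {} for sp in sorted(species)}
    history = TrueHistory()
    for family in sorted(families):
        tree = families[family]
        if tree is None:
            continue
        template = templates[family]
        for sp, seq_id in sorted(gene_leaves(tree)):
            lo, hi = cfg.flank_range
            left = random_protein(int(rng.integers(lo, hi + 1)), rng)
            right = random_protein(int(rng.integers(lo, hi + 1)), rng)
            domain = mutate(template, cfg.domain_divergence, rng)
            proteomes[sp][seq_id] = left + domain + right
            start = len(left)
            history.domains[seq_id] = [(start, start + len(template), family)]
    for sp in sorted(proteomes):
        lo, hi = cfg.decoy_length_range
        for k in range(cfg.decoys_per_proteome):
            seq_id = f"{sp}{SPECIES_GENE_SEP}decoy{k + 1}"
            proteomes[sp][seq_id] = random_protein(int(rng.integers(lo, hi + 1)), rng)
            history.domains[seq_id] = []
    return proteomes, history


def simulate_luminescence(true_ca: CalciumTrace,
                          constants: CalibrationConstants,
                          total_counts: float,
                          dt: float,
                          noise: bool = False,
                          seed: int = 0) -> tuple[LuminescenceTrace, TrueHistory]:
    """Forward-simulate aequorin photon counts from a known Ca2+ series.

    Inverts the calibration: x = (1 + K_R*Ca) / (1 + K_TR + K_R*Ca) gives the
    active-state fraction; the fractional consumption rate is R = x^n / lam
    per second.  Expected counts in bin i are R_i * A_i * dt with A the
    remaining reporter pool, which is decremented by its *expected*
    consumption (so the forward model stays exactly invertible); the
    unconsumed pool is reported as the post-lysis residual.  ``noise=True``
    Poisson-samples the emitted counts (and the residual) around these
    expectations.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if total_counts <= 0:
        raise ValueError("total_counts must be > 0")
    ca = np.asarray(true_ca.ca, dtype=float)
    if np.any(ca < 0):
        raise ValueError("true Ca2+ must be non-negative")
    x = (1.0 + constants.k_r * ca) / (1.0 + constants.k_tr + constants.k_r * ca)
    rate = np.power(x, constants.n) / constants.lam
    if np.any(rate * dt >= 1.0):
        raise ValueError("dt too large: a bin would consume the entire pool")
    expected = np.empty_like(rate)
    pool = float(total_counts)
    for i, r in enumerate(rate):
        expected[i] = r * pool * dt
        pool -= expected[i]
    rng = np.random.default_rng(seed)
    if noise:
        counts = rng.poisson(expected).astype(float)
        lysis = float(rng.poisson(pool))
    else:
        counts = expected
        lysis = pool
    times = np.arange(len(ca)) * dt
    trace = LuminescenceTrace(times, counts, lysis,
                              meta={"dt": dt, "seed": seed, "noise": noise,
                                    "total_counts": total_counts})
    return trace, TrueHistory(true_ca=true_ca)


def bell_transient(n: int = 240, dt: float = 0.5, onset: float = 10.0,
                   peak_ca: float = 5e-5, rise_tau: float = 4.0,
                   decay_tau: float = 20.0) -> CalciumTrace:
    """Smooth bell-shaped Ca2+ transient (double-exponential after onset).

    Defaults emulate a glucose-induced mitochondrial Ca2+ transient sampled
    every 0.5 s: ~50 uM peak, fast rise, slower decay, zero baseline.
    """
    t = np.arange(n) * dt
    s = np.clip(t - onset, 0.0, None)
    shape = (1.0 - np.exp(-s / rise_tau)) * np.exp(-s / decay_tau)
    shape[t < onset] = 0.0
    if shape.max() > 0:
        shape = shape / shape.max()
    return CalciumTrace(t, peak_ca * shape)
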
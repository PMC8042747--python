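"""Synthetic gene trees, traits and permutation nulls.

The generator emulates the structure of time-calibrated vertebrate gene
trees: each gene lineage descends an ultrametric species tree (default an
eight-species ladder whose root speciation is 296 My old), bifurcating at
every speciation age and additionally at Poisson-distributed duplication
times; duplicate copies may be lost.  Duplications can also be placed above
the species root ("ancient" duplications, older than every speciation),
which is where real time calibrations lack constraints — an optional bias
switch stretches the branches descending from such old-duplication nodes by
log-uniform factors, mimicking that unconstrained calibration.

Traits are simulated by exact Gaussian transitions along branches: plain
Brownian motion (BM1), duplication-accelerated BM ("ortholog conjecture",
rate multiplied by rho on branches below duplication nodes), per-regime BM
(BMM), and single- or multi-optimum Ornstein-Uhlenbeck.  Traits are
unbounded (no clamping to the empirical [0, 1] range of tau).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gene_trees import Event, GeneTree, Node, TraitTable, node_metrics
from .trait_models import paint_regimes

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "DEFAULT_SPECIATION_AGES",
    "species_tree",
    "generate_gene_tree",
    "generate_study",
    "inject_calibration_bias",
    "simulate_trait",
    "permute_tip_traits",
    "permute_node_events",
    "random_event_tree",
]

#: default species-tree speciation ages (My, root first); the root age is
#: the oldest speciation calibration point of the eight-vertebrate data set
DEFAULT_SPECIATION_AGES = (296.0, 167.0, 160.0, 90.0, 29.0, 9.0, 6.0)

MAX_TIPS = 10_000


@dataclass
class SimulationConfig:
    """Study-level simulation settings.

    dup_rate is the within-species-tree duplication rate (events per lineage
    per My); ancient_rate places duplications older than the species root,
    uniformly in (root age, ancient_max_age].  loss_prob is the probability
    that a newly created duplicate subtree is lost entirely.  trait_model is
    one of BM1, OC, BMM, OU1, OUM with its parameters; oc_rho >= 1 is the
    rate multiplier on post-duplication branches under OC.  bias_* control
    the calibration-bias injection on old-duplication branches.
    """

    speciation_ages: tuple[float, ...] = DEFAULT_SPECIATION_AGES
    dup_rate: float = 0.002
    ancient_rate: float = 0.002
    ancient_max_age: float = 1175.0
    loss_prob: float = 0.3
    trait_model: str = "BM1"
    sigma2: float = 0.01
    root_value: float = 0.5
    oc_rho: float = 4.0
    bmm_rates: dict | None = None  # Regime -> sigma^2
    ou_alpha: float = 0.01
    ou_thetas: dict | float = 0.5  # Regime -> theta, or single value
    bias_inject: bool = False
    bias_factor_low: float = 1.0
    bias_factor_high: float = 100.0
    n_trees: int = 50
    seed: int | None = None

    def __post_init__(self):
        if self.dup_rate < 0 or self.ancient_rate < 0:
            raise ValueError("duplication rates must be non-negative")
        if self.trait_model == "OC" and self.oc_rho < 1:
            raise ValueError("OC rate multiplier rho must be >= 1")
        if list(self.speciation_ages) != sorted(self.speciation_ages,
                                                reverse=True):
            raise ValueError("speciation ages must be in descending order")


@dataclass
class SimulatedStudy:
    """A batch of (gene tree, trait table) pairs with full provenance."""

    trees: list[GeneTree]
    traits: dict[str, TraitTable]  # tree_id -> traits
    config: SimulationConfig
    seed: int | None
    #: analysis trees: biased copies when bias injection is on, otherwise
    #: the same objects as ``trees``
    analysis_trees: list[GeneTree] = field(default_factory=list)

    def __post_init__(self):
        if not self.analysis_trees:
            self.analysis_trees = self.trees

    def pairs(self, biased: bool = True):
        source = self.analysis_trees if biased else self.trees
        return [(t, self.traits[t.tree_id]) for t in source]


# ---------------------------------------------------------------------------
# species tree and gene-tree generation
# ---------------------------------------------------------------------------

def species_tree(ages: tuple[float, ...] = DEFAULT_SPECIATION_AGES) -> GeneTree:
    """Ladder (pectinate) species tree from descending speciation ages.

    ``k`` ages give ``k + 1`` tips named S1..S(k+1); S(k+1) is the deepest
    outgroup.
    """
    n = len(ages) + 1
    # build from the most recent split outward
    left = Node(length=ages[-1], label="S1")
    right = Node(length=ages[-1], label="S2")
    node = Node(event=Event.SPECIATION)
    node.add_child(left)
    node.add_child(right)
    for i in range(len(ages) - 2, -1, -1):
        age = ages[i]
        node.length = age - ages[i + 1]
        parent = Node(event=Event.SPECIATION)
        parent.add_child(node)
        parent.add_child(Node(length=age, label=f"S{len(ages) - i + 1}"))
        node = parent
    node.length = None
    return GeneTree(node, tree_id="species")


def generate_gene_tree(config: SimulationConfig,
                       seed: int | np.random.Generator | None = None,
                       tree_id: str = "sim0") -> GeneTree:
    """Forward-simulate one gene tree down the configured species tree.

    Each gene lineage splits at every speciation age it traverses
    (SPECIATION node) and at Poisson(dup_rate)-distributed duplication times
    (DUPLICATION node); each new duplicate subtree is lost with
    ``loss_prob``.  Ancient duplications (ages above the species root) are
    drawn with intensity ``ancient_rate`` per My over
    (root age, ancient_max_age] and chained above the root.  The result is
    ultrametric with branch lengths in My and every internal node tagged.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    sp = species_tree(config.speciation_ages)
    sp_metrics = node_metrics(sp)
    root_age = config.speciation_ages[0]
    counter = [0]

    def tip_name(label: str) -> str:
        counter[0] += 1
        if counter[0] > MAX_TIPS:
            raise RuntimeError(f"simulated tree exceeds {MAX_TIPS} tips")
        # tree-id prefix keeps labels unique across a whole study, so the
        # trait tables of many trees can be merged into one file
        return f"{tree_id}.{label}_g{counter[0]}"

    def sim(sp_node: Node, start_age: float) -> tuple[Node, float]:
        """Simulate a gene lineage on species-tree node ``sp_node`` from
        ``start_age`` toward the present; returns (subtree top node, its
        age).  The caller sets the stem branch length."""
        end_age = 0.0 if sp_node.is_tip else sp_metrics[sp_node.id].age
        if config.dup_rate > 0:
            wait = rng.exponential(1.0 / config.dup_rate)
        else:
            wait = np.inf
        dup_age = start_age - wait
        if dup_age > end_age:
            # duplication before the next speciation / the present
            keep_copy = rng.random() >= config.loss_prob
            left, left_age = sim(sp_node, dup_age)
            if not keep_copy:
                return left, left_age  # lost copy leaves no node behind
            node = Node(event=Event.DUPLICATION)
            right, right_age = sim(sp_node, dup_age)
            for child, child_age in ((left, left_age), (right, right_age)):
                node.add_child(child)
                child.length = dup_age - child_age
            return node, dup_age
        if sp_node.is_tip:
            return Node(label=tip_name(sp_node.label)), 0.0
        node = Node(event=Event.SPECIATION)
        for sp_child in sp_node.children:
            child, child_age = sim(sp_child, end_age)
            node.add_child(child)
            child.length = end_age - child_age
        return node, end_age

    root, root_node_age = sim(sp.root, root_age)

    # ancient duplications above the species root
    if config.ancient_rate > 0 and config.ancient_max_age > root_age:
        span = config.ancient_max_age - root_age
        n_anc = rng.poisson(config.ancient_rate * span)
        ages = np.sort(rng.uniform(root_age, config.ancient_max_age,
                                   size=n_anc))  # ascending
        for age in ages:  # attach youngest first, chaining upward
            if rng.random() < config.loss_prob:
                continue  # the extra copy was lost: no node survives
            extra, extra_age = sim(sp.root, float(age))
            dup = Node(event=Event.DUPLICATION)
            dup.add_child(root)
            root.length = float(age) - root_node_age
            dup.add_child(extra)
            extra.length = float(age) - extra_age
            root = dup
            root_node_age = float(age)

    root.length = None
    return GeneTree(root, tree_id=tree_id)


def generate_study(config: SimulationConfig,
                   seed: int | None = None) -> SimulatedStudy:
    """Simulate a full study: trees, traits, and (optionally) biased copies.

    Traits are always simulated on the true (unbiased, ultrametric) trees;
    when ``config.bias_inject`` is set the returned ``analysis_trees`` are
    bias-injected copies, reproducing the situation where the trait evolved
    in real time but the analyst works with miscalibrated branch lengths.
    """
    if seed is None:
        seed = config.seed
    ss = np.random.SeedSequence(seed)
    trees: list[GeneTree] = []
    traits: dict[str, TraitTable] = {}
    analysis: list[GeneTree] = []
    child_seeds = ss.spawn(config.n_trees)
    threshold = config.speciation_ages[0]
    for i, cs in enumerate(child_seeds):
        rng = np.random.default_rng(cs)
        tree = generate_gene_tree(config, seed=rng, tree_id=f"sim{i}")
        traits[tree.tree_id] = simulate_trait(tree, config, seed=rng)
        trees.append(tree)
        if config.bias_inject:
            analysis.append(inject_calibration_bias(
                tree, seed=rng, age_threshold=threshold,
                factor_low=config.bias_factor_low,
                factor_high=config.bias_factor_high))
    return SimulatedStudy(trees=trees, traits=traits, config=config,
                          seed=seed, analysis_trees=analysis or trees)


# ---------------------------------------------------------------------------
# calibration bias
# ---------------------------------------------------------------------------

def inject_calibration_bias(
    tree: GeneTree,
    seed: int | np.random.Generator | None = None,
    age_threshold: float | None = None,
    factor_low: float = 1.0,
    factor_high: float = 100.0,
) -> GeneTree:
    """Stretch the branches descending from old-duplication nodes.

    Every branch whose parent node is a duplication older than
    ``age_threshold`` (default: the oldest speciation age in the tree; if
    none, the tree is returned unchanged) is multiplied by an independent
    log-uniform factor from [factor_low, factor_high].  This inflates the
    expected variances of contrasts taken at old duplication nodes — the
    signature of time calibrations with no constraint above the oldest
    speciation — and leaves everything below the threshold untouched.  The
    copy is flagged non-ultrametric.  A tree with no old duplications is
    returned as an unchanged copy.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    metrics = node_metrics(tree)
    if age_threshold is None:
        sp_ages = [metrics[n.id].age for n in tree.internal_nodes
                   if n.event is Event.SPECIATION]
        if not sp_ages:
            return tree.copy()
        age_threshold = max(sp_ages)
    old_ids = {n.id for n in tree.internal_nodes
               if n.event is Event.DUPLICATION
               and metrics[n.id].age > age_threshold}
    new = tree.copy()  # copy preserves node ids (same construction order)
    touched = False
    for node in new.nodes:
        if node.parent is not None and node.parent.id in old_ids:
            f = np.exp(rng.uniform(np.log(factor_low), np.log(factor_high)))
            if f != 1.0:
                node.length = node.length * float(f)
                touched = True
    if touched:
        new.ultrametric_expected = False
    return new


# ---------------------------------------------------------------------------
# trait simulation
# ---------------------------------------------------------------------------

def _branch_rates(tree: GeneTree, config: SimulationConfig) -> dict[int, float]:
    model = config.trait_model
    if model == "BM1":
        return {n.id: config.sigma2 for n in tree.nodes if n is not tree.root}
    if model == "OC":
        out = {}
        for node in tree.nodes:
            if node is tree.root:
                continue
            accel = node.parent.event is Event.DUPLICATION
            out[node.id] = config.sigma2 * (config.oc_rho if accel else 1.0)
        return out
    if model == "BMM":
        if not config.bmm_rates:
            raise ValueError("BMM simulation requires config.bmm_rates")
        painting = paint_regimes(tree, age_threshold=config.speciation_ages[0])
        return {nid: config.bmm_rates[reg]
                for nid, reg in painting.branch_states.items()}
    raise ValueError(f"unknown trait model {model!r}")


def simulate_trait(
    tree: GeneTree,
    config: SimulationConfig,
    seed: int | np.random.Generator | None = None,
) -> TraitTable:
    """Simulate one trait realisation on a tree by exact branch transitions.

    BM-family models add Normal(0, sigma^2_branch * length) increments; OU
    models use the exact transition
    Normal(x e^{-a l} + theta (1 - e^{-a l}), sigma^2/(2a) (1 - e^{-2a l})).
    The root starts at ``config.root_value`` (BM) or the root regime's
    optimum (OU).  Values are unbounded.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    model = config.trait_model
    values: dict[int, float] = {}
    if model in ("BM1", "OC", "BMM"):
        rates = _branch_rates(tree, config)
        values[tree.root.id] = config.root_value
        for node in tree.preorder():
            if node is tree.root:
                continue
            var = rates[node.id] * (node.length or 0.0)
            values[node.id] = values[node.parent.id] + (
                rng.normal(0.0, np.sqrt(var)) if var > 0 else 0.0)
    elif model in ("OU1", "OUM"):
        alpha = config.ou_alpha
        sigma2 = config.sigma2
        painting = paint_regimes(tree, age_threshold=config.speciation_ages[0])
        if isinstance(config.ou_thetas, dict):
            theta_of = lambda reg: config.ou_thetas[reg]
        else:
            theta_of = lambda reg: float(config.ou_thetas)
        values[tree.root.id] = theta_of(painting.root_regime)
        for node in tree.preorder():
            if node is tree.root:
                continue
            ln = node.length or 0.0
            theta = theta_of(painting.branch_states[node.id])
            x0 = values[node.parent.id]
            mean = x0 * np.exp(-alpha * ln) + theta * -np.expm1(-alpha * ln)
            var = sigma2 / (2 * alpha) * -np.expm1(-2 * alpha * ln)
            values[node.id] = mean + (rng.normal(0.0, np.sqrt(var))
                                      if var > 0 else 0.0)
    else:
        raise ValueError(f"unknown trait model {model!r}")
    return TraitTable({t.label: float(values[t.id]) for t in tree.tips},
                      name="tau_sim")


# ---------------------------------------------------------------------------
# permutation nulls
# ---------------------------------------------------------------------------

def permute_tip_traits(
    tree: GeneTree,
    traits: TraitTable,
    seed: int | np.random.Generator | None = None,
) -> TraitTable:
    """Uniform random permutation of trait values over the tree's tips.

    The multiset of values is preserved exactly; node events are untouched.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    labels = [t.label for t in tree.tips if t.label in traits]
    vals = [traits[lab] for lab in labels]
    perm = rng.permutation(len(vals))
    new = dict(traits.values)
    for lab, j in zip(labels, perm):
        new[lab] = vals[j]
    return TraitTable(new, name=traits.name)


def permute_node_events(
    tree: GeneTree,
    seed: int | np.random.Generator | None = None,
) -> GeneTree:
    """Uniform random permutation of the internal-node event multiset.

    Event counts per category are preserved exactly; branch lengths and tip
    traits are untouched.  Duplication age classes must be re-derived on the
    returned tree (node ages are unchanged but which nodes are duplications
    is not).
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    new = tree.copy()
    internals = new.internal_nodes
    events = [n.event for n in internals]
    perm = rng.permutation(len(events))
    for node, j in zip(internals, perm):
        node.event = events[j]
    return new


# ---------------------------------------------------------------------------
# auxiliary random trees (for oracles and calibration experiments)
# ---------------------------------------------------------------------------

def random_event_tree(
    n_tips: int,
    height: float = 100.0,
    p_dup: float = 0.3,
    seed: int | np.random.Generator | None = None,
    tree_id: str = "rand0",
) -> GeneTree:
    """Random ultrametric tree with randomly event-tagged internal nodes.

    Topology and node times follow a simple coalescent-style construction:
    n tips at time 0 merge in random pairs at uniformly ordered times up to
    ``height``.  Each internal node is tagged DUPLICATION with probability
    ``p_dup``, else SPECIATION.  Useful for likelihood oracles and
    calibration studies where the species-tree structure is irrelevant.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    times = np.sort(rng.uniform(0.0, height, size=n_tips - 1))
    times[-1] = height
    lineages: list[tuple[Node, float]] = [
        (Node(label=f"t{i + 1}"), 0.0) for i in range(n_tips)]
    for t in times:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        (a, ta) = lineages[i]
        (b, tb) = lineages.pop(j)
        lineages.pop(i)
        ev = Event.DUPLICATION if rng.random() < p_dup else Event.SPECIATION
        parent = Node(event=ev)
        a.length = t - ta
        b.length = t - tb
        parent.add_child(a)
        parent.add_child(b)
        lineages.append((parent, float(t)))
    root = lineages[0][0]
    root.length = None
    return GeneTree(root, tree_id=tree_id)
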
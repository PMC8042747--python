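"""Phylogenetic independent contrasts, phylogenetic signal, and the
contrast-standardization diagnostics that gate their use.

A PIC at an internal node is the difference between the two descendant trait
values divided by its expected standard deviation, the square root of the
summed (variance-adjusted) child branch lengths.  Under Brownian motion on
the true tree, PICs are iid Normal(0, sigma^2); any correlation between
|PIC| and the expected SD, node age, node height or node depth signals a
violation (wrong branch lengths or a non-Brownian process) and makes naive
contrast comparisons unsafe.  When the diagnostics fail, a power
transformation of the branch lengths (b -> b^e for e in 0..2, or log10 b)
can restore adequate standardization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .gene_trees import Event, GeneTree, TraitTable, node_metrics

__all__ = [
    "ContrastRecord",
    "SignalResult",
    "DiagnosticTest",
    "DiagnosticsResult",
    "TransformResult",
    "compute_pic",
    "blomberg_k",
    "diagnostics",
    "transform_branch_lengths",
    "phylogenetic_covariance",
    "TRANSFORM_EXPONENTS",
    "K_STRONG_SIGNAL_CUTOFF",
]

#: published cutoff above which a tree is taken to show strong
#: phylogenetic signal for the trait
K_STRONG_SIGNAL_CUTOFF = 0.551

#: candidate branch-length power exponents, 0 to 2 in steps of 0.1
TRANSFORM_EXPONENTS = tuple(round(0.1 * i, 1) for i in range(21))

DIAGNOSTIC_PREDICTORS = ("expected_sd", "log_node_age", "node_height", "node_depth")


@dataclass
class ContrastRecord:
    """One standardized contrast with the metadata used downstream."""

    tree_id: str
    node_id: int
    event: Event
    age_class: str | None  # "young"/"old" for duplications, else None
    contrast: float  # standardized PIC, trait units per sqrt(My)
    expected_sd: float  # sqrt(v1 + v2), sqrt(My)
    ancestral_value: float
    node_age: float
    node_height: float
    node_depth: int

    @property
    def abs_contrast(self) -> float:
        return abs(self.contrast)


@dataclass
class SignalResult:
    """Blomberg's K with its permutation test."""

    k: float  # nan when the trait is invariant
    p_value: float
    n_permutations: int
    strong_signal: bool
    cutoff: float = K_STRONG_SIGNAL_CUTOFF

    @property
    def defined(self) -> bool:
        return math.isfinite(self.k)


@dataclass
class DiagnosticTest:
    predictor: str
    r: float
    p: float
    n: int
    degenerate: bool = False  # zero-variance predictor or response

    @property
    def passed(self) -> bool:
        return self.degenerate or self.p >= self._alpha

    _alpha: float = 0.05


@dataclass
class DiagnosticsResult:
    """Outcome of the four-test contrast-standardization battery.

    ``passed`` is True iff every test has p >= alpha (degenerate tests pass
    vacuously).  ``evaluable`` is False with fewer than 3 contrasts.
    """

    tests: list[DiagnosticTest]
    alpha: float
    evaluable: bool = True
    notes: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.evaluable and all(t.passed for t in self.tests)

    def test(self, predictor: str) -> DiagnosticTest:
        return next(t for t in self.tests if t.predictor == predictor)


@dataclass
class TransformResult:
    """Chosen branch-length transformation and its post-transform check."""

    exponent: float | str | None  # 0.0..2.0, "log10", or None (= none found)
    transformed_tree: GeneTree | None
    diagnostics: DiagnosticsResult | None
    sd_correlations: dict  # candidate -> (r, p)
    excluded: bool = False


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------

def _tree_arrays(tree: GeneTree):
    """Flat postorder representation: (internal ids, child1, child2, lengths,
    tip ids, tip labels). Node ids index the arrays."""
    n = len(tree.nodes)
    child1 = np.full(n, -1, dtype=np.intp)
    child2 = np.full(n, -1, dtype=np.intp)
    lengths = np.zeros(n)
    tip_ids, tip_labels, internal_ids = [], [], []
    for node in tree.postorder():
        if node.length is not None:
            lengths[node.id] = node.length
        if node.is_tip:
            tip_ids.append(node.id)
            tip_labels.append(node.label)
        else:
            internal_ids.append(node.id)
            child1[node.id] = node.children[0].id
            child2[node.id] = node.children[1].id
    return (np.asarray(internal_ids, dtype=np.intp), child1, child2, lengths,
            np.asarray(tip_ids, dtype=np.intp), tip_labels)


def _pic_core(internal_ids, child1, child2, lengths, tip_ids, tip_values):
    """Felsenstein's pruning pass on flat arrays.

    Returns (contrasts, expected_sd, ancestral values) indexed like
    ``internal_ids``.  Raises on a degenerate zero expected variance.
    """
    n = len(lengths)
    x = np.zeros(n)
    v = lengths.astype(float).copy()
    x[tip_ids] = tip_values
    m = len(internal_ids)
    u = np.empty(m)
    sd = np.empty(m)
    anc = np.empty(m)
    for j in range(m):
        i = internal_ids[j]
        c1 = child1[i]
        c2 = child2[i]
        v1 = v[c1]
        v2 = v[c2]
        vs = v1 + v2
        if vs <= 0.0:
            raise ValueError("zero expected variance at an internal node "
                             "(both child branches have length 0)")
        s = math.sqrt(vs)
        u[j] = (x[c1] - x[c2]) / s
        sd[j] = s
        a = (x[c1] * v2 + x[c2] * v1) / vs  # == (x1/v1+x2/v2)/(1/v1+1/v2)
        x[i] = a
        anc[j] = a
        v[i] += v1 * v2 / vs
    return u, sd, anc


def compute_pic(
    tree: GeneTree,
    traits: TraitTable,
    age_classes: dict[int, str] | None = None,
) -> list[ContrastRecord]:
    """Compute one standardized contrast per internal node (n-1 for n tips).

    ``age_classes`` optionally maps duplication node id -> "young"/"old"
    (from :func:`~paracontrast.gene_trees.classify_duplication_ages`).
    Raises ``KeyError`` listing tips that lack trait values.
    """
    internal_ids, child1, child2, lengths, tip_ids, tip_labels = _tree_arrays(tree)
    missing = [lab for lab in tip_labels if lab not in traits]
    if missing:
        raise KeyError(f"tips without trait values: {missing}")
    tip_values = np.array([traits[lab] for lab in tip_labels])
    u, sd, anc = _pic_core(internal_ids, child1, child2, lengths, tip_ids,
                           tip_values)
    metrics = node_metrics(tree)
    nodes = tree.nodes
    records = []
    for j, i in enumerate(internal_ids):
        node = nodes[i]
        age_class = None
        if node.event is Event.DUPLICATION and age_classes is not None:
            age_class = age_classes.get(node.id)
        m = metrics[node.id]
        records.append(ContrastRecord(
            tree_id=tree.tree_id, node_id=int(node.id), event=node.event,
            age_class=age_class, contrast=float(u[j]), expected_sd=float(sd[j]),
            ancestral_value=float(anc[j]), node_age=m.age, node_height=m.height,
            node_depth=m.depth,
        ))
    return records


# ---------------------------------------------------------------------------
# phylogenetic signal
# ---------------------------------------------------------------------------

def phylogenetic_covariance(tree: GeneTree) -> tuple[np.ndarray, list[str]]:
    """Matrix C of shared root-to-MRCA path lengths between tips.

    C[i, i] is the root-to-tip distance; C[i, j] the root-to-MRCA distance.
    Returns (C, tip labels in matrix order).
    """
    heights = tree.heights()
    tips = tree.tips
    order = {t.id: k for k, t in enumerate(tips)}
    n = len(tips)
    C = np.zeros((n, n))
    tipsets: dict[int, list[int]] = {}
    for node in tree.postorder():
        if node.is_tip:
            k = order[node.id]
            C[k, k] = heights[node.id]
            tipsets[node.id] = [k]
        else:
            h = heights[node.id]
            sets = [tipsets.pop(c.id) for c in node.children]
            for a_i in range(len(sets)):
                for b_i in range(a_i + 1, len(sets)):
                    for a in sets[a_i]:
                        for b in sets[b_i]:
                            C[a, b] = C[b, a] = h
            merged = [k for s in sets for k in s]
            tipsets[node.id] = merged
    return C, [t.label for t in tips]


def blomberg_k(
    tree: GeneTree,
    traits: TraitTable,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    cutoff: float = K_STRONG_SIGNAL_CUTOFF,
) -> SignalResult:
    """Blomberg's K with a tip-permutation test of phylogenetic signal.

    K is the ratio of (MSE0/MSE) observed to its Brownian expectation, where
    MSE0 uses the raw deviations from the phylogenetic mean and MSE the
    C-whitened ones; K ~ 1 under BM on the true tree, ~ 0 with no signal.
    The permutation p-value is the share of tip relabelings whose MSE is at
    most the observed one (with add-one correction), small MSE meaning
    strong signal.  An invariant trait gives an undefined K (NaN).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    C, labels = phylogenetic_covariance(tree)
    x = np.array([traits[lab] for lab in labels])
    n = len(x)
    if n < 4:
        raise ValueError("Blomberg's K requires at least 4 tips with traits")
    if np.ptp(x) == 0.0:
        return SignalResult(k=float("nan"), p_value=1.0, n_permutations=0,
                            strong_signal=False, cutoff=cutoff)
    Cinv = np.linalg.inv(C)
    ones = np.ones(n)
    w = Cinv @ ones
    denom_a = ones @ w
    expected_ratio = (np.trace(C) - n / denom_a) / (n - 1)

    def mse_pair(vec: np.ndarray) -> tuple[float, float]:
        a_hat = (w @ vec) / denom_a
        r = vec - a_hat
        return float(r @ r) / (n - 1), float(r @ Cinv @ r) / (n - 1)

    mse0, mse = mse_pair(x)
    k = (mse0 / mse) / expected_ratio
    if n_perm > 0:
        count = 0
        for _ in range(n_perm):
            _, mse_p = mse_pair(rng.permutation(x))
            if mse_p <= mse:
                count += 1
        p = (count + 1) / (n_perm + 1)
    else:
        p = float("nan")
    return SignalResult(k=float(k), p_value=p, n_permutations=n_perm,
                        strong_signal=k > cutoff, cutoff=cutoff)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """(r, p, degenerate) for a Pearson correlation; fast path for the
    diagnostic loops."""
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(xc @ xc)
    sy = float(yc @ yc)
    if sx <= 0.0 or sy <= 0.0 or n < 3:
        return 0.0, 1.0, True
    r = float(xc @ yc) / math.sqrt(sx * sy)
    r = max(-1.0, min(1.0, r))
    df = n - 2
    if abs(r) == 1.0:
        return r, 0.0, False
    t = r * math.sqrt(df / (1.0 - r * r))
    p = 2.0 * float(special.stdtr(df, -abs(t)))
    return r, p, False


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0, 1.0, True
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue), False


def diagnostics(
    records: list[ContrastRecord],
    alpha: float = 0.05,
    method: str = "pearson",
) -> DiagnosticsResult:
    """Four correlation tests of |contrast| against expected SD, log10 node
    age, node height and node depth.

    The battery passes iff every test has p >= alpha.  A zero-variance
    predictor or response passes vacuously (recorded as degenerate);
    nodes with age <= 0 are dropped from the age test only.
    """
    corr = _pearson if method == "pearson" else _spearman
    if len(records) < 3:
        return DiagnosticsResult(tests=[], alpha=alpha, evaluable=False,
                                 notes=["fewer than 3 contrasts"])
    absu = np.array([r.abs_contrast for r in records])
    notes: list[str] = []
    tests: list[DiagnosticTest] = []
    predictors = {
        "expected_sd": np.array([r.expected_sd for r in records]),
        "node_height": np.array([r.node_height for r in records]),
        "node_depth": np.array([float(r.node_depth) for r in records]),
    }
    ages = np.array([r.node_age for r in records])
    pos = ages > 0
    if not pos.all():
        notes.append(f"{int((~pos).sum())} nodes with age <= 0 dropped "
                     "from the age test")
    for name in DIAGNOSTIC_PREDICTORS:
        if name == "log_node_age":
            if pos.sum() < 3:
                tests.append(DiagnosticTest(name, 0.0, 1.0, int(pos.sum()),
                                            degenerate=True))
                continue
            r, p, degen = corr(np.log10(ages[pos]), absu[pos])
            nn = int(pos.sum())
        else:
            r, p, degen = corr(predictors[name], absu)
            nn = len(records)
        tests.append(DiagnosticTest(name, r, p, nn, degenerate=degen))
    for t in tests:
        t._alpha = alpha
    return DiagnosticsResult(tests=tests, alpha=alpha, notes=notes)


# ---------------------------------------------------------------------------
# branch-length transformation
# ---------------------------------------------------------------------------

def _transformed_copy(tree: GeneTree, candidate: float | str) -> GeneTree:
    new = tree.copy()
    for node in new.nodes:
        if node is new.root or node.length is None:
            continue
        if candidate == "log10":
            node.length = math.log10(node.length)
        else:
            node.length = node.length ** candidate
    new.ultrametric_expected = False
    return new


def transform_branch_lengths(
    tree: GeneTree,
    traits: TraitTable,
    alpha: float = 0.05,
    method: str = "pearson",
) -> TransformResult:
    """Search the power family b^e, e in {0, 0.1, ..., 2}, plus log10(b),
    for a transformation giving adequately standardized contrasts.

    For each candidate the |contrast|-vs-expected-SD correlation is computed
    on the transformed tree; among candidates with p >= alpha the one with
    the smallest |r| is chosen (ties broken toward the exponent closest to
    1, then the smaller).  log10 is only admissible when every branch is
    longer than 1 My (shorter branches would transform to non-positive
    lengths).  If no candidate passes, the tree is flagged for exclusion.
    The chosen tree is re-checked with the full four-test battery.
    """
    internal_ids, child1, child2, lengths, tip_ids, tip_labels = _tree_arrays(tree)
    missing = [lab for lab in tip_labels if lab not in traits]
    if missing:
        raise KeyError(f"tips without trait values: {missing}")
    nonroot = np.ones(len(lengths), dtype=bool)
    nonroot[tree.root.id] = False
    if np.any(lengths[nonroot] <= 0.0):
        raise ValueError("branch-length transformation requires strictly "
                         "positive branch lengths")
    tip_values = np.array([traits[lab] for lab in tip_labels])

    candidates: list[float | str] = list(TRANSFORM_EXPONENTS)
    if lengths[nonroot].min() > 1.0:
        candidates.append("log10")

    sd_correlations: dict = {}
    admissible: list[tuple[float, float, float | str]] = []
    for cand in candidates:
        tl = np.log10(lengths, where=nonroot, out=np.zeros_like(lengths)) \
            if cand == "log10" else lengths ** cand
        u, sd, _ = _pic_core(internal_ids, child1, child2, tl, tip_ids,
                             tip_values)
        r, p, degen = _pearson(sd, np.abs(u)) if method == "pearson" \
            else _spearman(sd, np.abs(u))
        sd_correlations[cand] = (r, p)
        if degen or p >= alpha:
            admissible.append((abs(r), _tie_key(cand), cand))
    if not admissible:
        return TransformResult(exponent=None, transformed_tree=None,
                               diagnostics=None,
                               sd_correlations=sd_correlations, excluded=True)
    admissible.sort(key=lambda t: (t[0], t[1]))
    chosen = admissible[0][2]
    new_tree = _transformed_copy(tree, chosen)
    recs = compute_pic(new_tree, traits)
    diag = diagnostics(recs, alpha=alpha, method=method)
    return TransformResult(exponent=chosen, transformed_tree=new_tree,
                           diagnostics=diag, sd_correlations=sd_correlations)


def _tie_key(cand: float | str) -> tuple[float, float]:
    # ties: prefer exponent closest to 1, then the smaller; log10 sorts last
    if cand == "log10":
        return (math.inf, math.inf)
    return (abs(cand - 1.0), cand)
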
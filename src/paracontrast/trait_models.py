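"""Multi-regime Brownian-motion and Ornstein-Uhlenbeck models of trait
evolution on event-painted gene trees.

Each branch is painted with the event class of its parent (ancestral) node —
speciation, young duplication, old duplication, or NA — and four models are
fitted by maximum likelihood:

* BM1: single Brownian rate sigma^2 and root mean mu.
* BMM: one Brownian rate per regime.
* OU1: single-optimum Ornstein-Uhlenbeck (alpha, sigma^2, theta).
* OUM: multi-optimum OU with shared alpha and sigma^2 but one theta per
  regime.

All are Gaussian models: BM covariance accumulates sigma^2_k * branch time
along shared root paths; the OU covariance is sigma^2/(2 alpha) *
exp(-alpha d_ij) * (1 - exp(-2 alpha t_ij)) for a fixed (non-random) root,
or sigma^2/(2 alpha) * exp(-alpha d_ij) for a stationary root, with d the
patristic distance and t the root-to-MRCA time.  The OU mean weights each
regime's optimum by the fraction of adaptation toward it accumulated along
each tip's root path.  Models are compared per tree with small-sample AICc
and Akaike weights; a fit counts as converged only when the optimizer
succeeded and the Hessian of the negative log-likelihood at the optimum is
positive definite.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

from .gene_trees import Event, GeneTree, TraitTable, node_metrics

__all__ = [
    "Regime",
    "RegimePainting",
    "ModelFit",
    "TreeModelReport",
    "MODEL_NAMES",
    "paint_regimes",
    "bm_loglik",
    "ou_loglik",
    "fit_model",
    "fit_all_models",
    "select_model",
    "aicc",
]

MODEL_NAMES = ("BM1", "BMM", "OU1", "OUM")

ALPHA_MIN = 1e-8  # 1/My; below this OU is numerically Brownian


class Regime(enum.Enum):
    SPECIATION = "speciation"
    DUP_YOUNG = "young-duplication"
    DUP_OLD = "old-duplication"
    NA = "na"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


_REGIME_ORDER = (Regime.SPECIATION, Regime.DUP_YOUNG, Regime.DUP_OLD, Regime.NA)


@dataclass
class RegimePainting:
    """Branch -> regime map; a branch is identified by its child node id."""

    branch_states: dict[int, Regime]
    root_regime: Regime

    @property
    def regimes(self) -> tuple[Regime, ...]:
        present = set(self.branch_states.values())
        return tuple(r for r in _REGIME_ORDER if r in present)

    @property
    def m(self) -> int:
        return len(self.regimes)


@dataclass
class ModelFit:
    """One fitted trait-evolution model for one tree."""

    model: str
    params: dict
    loglik: float
    k: int  # free-parameter count
    n: int  # tips
    aicc: float
    converged: bool
    weight: float | None = None  # Akaike weight, set by select_model
    message: str = ""


@dataclass
class TreeModelReport:
    tree_id: str | None
    fits: list[ModelFit]
    status: str  # "ok" | "trait-invariant" | "all-models-failed"
    best: ModelFit | None = None


def _event_regime(node, age_classes: dict[int, str]) -> Regime:
    if node.event is Event.SPECIATION:
        return Regime.SPECIATION
    if node.event is Event.DUPLICATION:
        return Regime.DUP_OLD if age_classes.get(node.id) == "old" \
            else Regime.DUP_YOUNG
    return Regime.NA


def paint_regimes(
    tree: GeneTree,
    age_threshold: float | None = None,
    age_classes: dict[int, str] | None = None,
) -> RegimePainting:
    """Assign each branch the event class of its parent node.

    Duplications are split young/old at ``age_threshold`` My (boundary
    inclusive for young), or by a precomputed ``age_classes`` map from
    :func:`~paracontrast.gene_trees.classify_duplication_ages`.
    """
    if age_classes is None:
        if age_threshold is None:
            raise ValueError("either age_threshold or age_classes is required")
        metrics = node_metrics(tree)
        age_classes = {
            n.id: ("young" if metrics[n.id].age <= age_threshold else "old")
            for n in tree.internal_nodes if n.event is Event.DUPLICATION
        }
    states: dict[int, Regime] = {}
    for node in tree.internal_nodes:
        reg = _event_regime(node, age_classes)
        for child in node.children:
            states[child.id] = reg
    return RegimePainting(branch_states=states,
                          root_regime=_event_regime(tree.root, age_classes))


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

class _LikContext:
    """Per-(tree, painting) precomputation for the Gaussian likelihoods."""

    def __init__(self, tree: GeneTree, painting: RegimePainting):
        self.painting = painting
        self.regimes = painting.regimes
        reg_index = {r: k for k, r in enumerate(self.regimes)}
        heights = tree.heights()
        tips = tree.tips
        self.tip_labels = [t.label for t in tips]
        order = {t.id: k for k, t in enumerate(tips)}
        n = len(tips)
        m = len(self.regimes)
        # per-node regime time from the root
        tvec: dict[int, np.ndarray] = {tree.root.id: np.zeros(m)}
        for node in tree.preorder():
            if node is tree.root:
                continue
            v = tvec[node.parent.id].copy()
            v[reg_index[painting.branch_states[node.id]]] += node.length or 0.0
            tvec[node.id] = v
        # per-regime shared-time matrices
        Ck = np.zeros((m, n, n))
        tipsets: dict[int, list[int]] = {}
        for node in tree.postorder():
            if node.is_tip:
                k = order[node.id]
                Ck[:, k, k] = tvec[node.id]
                tipsets[node.id] = [k]
            else:
                tv = tvec[node.id]
                sets = [tipsets.pop(c.id) for c in node.children]
                for ai in range(len(sets)):
                    for bi in range(ai + 1, len(sets)):
                        for a in sets[ai]:
                            for b in sets[bi]:
                                Ck[:, a, b] = Ck[:, b, a] = tv
                tipsets[node.id] = [k for s in sets for k in s]
        self.Ck = Ck
        self.C = Ck.sum(axis=0)  # total shared time
        self.t_mrca = self.C  # alias: root-to-MRCA time matrix
        self.T = np.diag(self.C).copy()  # per-tip root-to-tip time
        self.d = self.T[:, None] + self.T[None, :] - 2.0 * self.C  # patristic
        self.n = n
        self.m = m
        # root-path segments per tip: (regime index, h0, h1), h from root
        self.segments: list[list[tuple[int, float, float]]] = []
        for t in tips:
            segs = []
            node = t
            while node is not tree.root:
                h1 = heights[node.id]
                h0 = heights[node.parent.id]
                segs.append((reg_index[painting.branch_states[node.id]], h0, h1))
                node = node.parent
            self.segments.append(segs)
        self.root_reg_index = (reg_index[painting.root_regime]
                               if painting.root_regime in reg_index else None)

    def trait_vector(self, traits: TraitTable) -> np.ndarray:
        missing = [lab for lab in self.tip_labels if lab not in traits]
        if missing:
            raise KeyError(f"tips without trait values: {missing}")
        return np.array([traits[lab] for lab in self.tip_labels])

    # -- BM ---------------------------------------------------------------

    def bm_cov(self, sigma2s: np.ndarray) -> np.ndarray:
        return np.tensordot(sigma2s, self.Ck, axes=1)

    def bm_loglik(self, x: np.ndarray, sigma2s: np.ndarray, mu: float) -> float:
        return _mvn_loglik(x, np.full(self.n, mu), self.bm_cov(sigma2s))

    # -- OU ---------------------------------------------------------------

    def ou_weights(self, alpha: float) -> np.ndarray:
        """W[i, k]: weight of regime k's optimum in tip i's expectation.

        Integrates alpha * exp(-alpha (T_i - t)) over the times spent in
        regime k along tip i's root path; rows sum to 1 - exp(-alpha T_i).
        """
        W = np.zeros((self.n, self.m))
        for i, segs in enumerate(self.segments):
            Ti = self.T[i]
            for k, h0, h1 in segs:
                W[i, k] += math.exp(-alpha * (Ti - h1)) - math.exp(-alpha * (Ti - h0))
        return W

    def ou_design(self, alpha: float, root: str) -> np.ndarray:
        """Design matrix X with E[x] = X @ theta."""
        W = self.ou_weights(alpha)
        if root == "fixed":
            if self.root_reg_index is None:
                raise ValueError("root regime absent from painting")
            W[:, self.root_reg_index] += np.exp(-alpha * self.T)
        elif root == "stationary":
            # the stationary root value itself is centred on the root
            # regime's optimum, so the missing weight goes there too
            W[:, self.root_reg_index] += np.exp(-alpha * self.T)
        else:
            raise ValueError(f"unknown root option {root!r}")
        return W

    def ou_cov0(self, alpha: float, root: str) -> np.ndarray:
        """OU covariance for sigma^2 = 1."""
        if root == "fixed":
            V = np.exp(-alpha * self.d) * (-np.expm1(-2.0 * alpha * self.t_mrca))
        else:
            V = np.exp(-alpha * self.d)
        return V / (2.0 * alpha)

    def ou_loglik(self, x: np.ndarray, alpha: float, sigma2: float,
                  thetas: np.ndarray, root: str) -> float:
        mean = self.ou_design(alpha, root) @ thetas
        return _mvn_loglik(x, mean, sigma2 * self.ou_cov0(alpha, root))


def _mvn_loglik(x: np.ndarray, mean: np.ndarray, V: np.ndarray) -> float:
    n = len(x)
    try:
        L = linalg.cholesky(V, lower=True)
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError(
            "singular trait covariance matrix (duplicate zero-distance tips?)"
        ) from exc
    r = linalg.solve_triangular(L, x - mean, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return float(-0.5 * (n * math.log(2.0 * math.pi) + logdet + r @ r))


def _gls(X: np.ndarray, x: np.ndarray, V: np.ndarray):
    """GLS estimate, residual quadratic form and log|V| via Cholesky.

    Returns (beta, rss = r' V^-1 r, logdet) or None if V is not PD.
    """
    try:
        L = linalg.cholesky(V, lower=True)
    except linalg.LinAlgError:
        return None
    Xw = linalg.solve_triangular(L, X, lower=True)
    xw = linalg.solve_triangular(L, x, lower=True)
    # least squares tolerates the rank deficiency of nearly collinear
    # OU design columns at very small alpha
    beta = np.linalg.lstsq(Xw, xw, rcond=None)[0]
    r = xw - Xw @ beta
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return beta, float(r @ r), logdet


# ---------------------------------------------------------------------------
# public likelihood operations
# ---------------------------------------------------------------------------

def _as_rate_vector(painting: RegimePainting, rates) -> np.ndarray:
    if isinstance(rates, dict):
        vec = np.array([rates[r] for r in painting.regimes], dtype=float)
    else:
        vec = np.full(painting.m, float(rates))
    if np.any(vec <= 0):
        raise ValueError("all Brownian rates must be positive")
    return vec


def bm_loglik(tree: GeneTree, traits: TraitTable, painting: RegimePainting,
              rates, mu: float) -> float:
    """Exact log-density of the tip traits under (multi-rate) Brownian
    motion.  ``rates`` is a scalar (BM1) or a dict regime -> sigma^2."""
    ctx = _LikContext(tree, painting)
    return ctx.bm_loglik(ctx.trait_vector(traits),
                         _as_rate_vector(painting, rates), mu)


def ou_loglik(tree: GeneTree, traits: TraitTable, painting: RegimePainting,
              alpha: float, sigma2: float, optima,
              root: str = "fixed") -> float:
    """Exact log-density under a (multi-optimum) Ornstein-Uhlenbeck model.

    ``optima`` is a scalar (OU1) or a dict regime -> theta.  ``root`` is
    "fixed" (root state pinned at the root-adjacent regime's optimum) or
    "stationary".
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive; use bm_loglik for the limit")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    ctx = _LikContext(tree, painting)
    if isinstance(optima, dict):
        thetas = np.array([optima[r] for r in painting.regimes], dtype=float)
    else:
        thetas = np.full(painting.m, float(optima))
    return ctx.ou_loglik(ctx.trait_vector(traits), alpha, sigma2, thetas, root)


def aicc(loglik: float, k: int, n: int) -> float:
    """Second-order Akaike information criterion."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _fit_bm1(ctx: _LikContext, x: np.ndarray) -> tuple[dict, float]:
    res = _gls(np.ones((ctx.n, 1)), x, ctx.C)
    if res is None:
        raise linalg.LinAlgError("singular BM covariance")
    beta, rss, logdet = res
    sigma2 = rss / ctx.n
    mu = float(beta[0])
    ll = -0.5 * (ctx.n * math.log(2 * math.pi * sigma2) + logdet + ctx.n)
    return {"sigma2": sigma2, "mu": mu}, ll


def _bmm_profile_nll(ctx: _LikContext, x: np.ndarray, log_rel: np.ndarray):
    """NLL profiled over the overall scale and mu; log_rel are log relative
    rates of regimes 2..m (regime 1 fixed at 1)."""
    rel = np.concatenate([[1.0], np.exp(log_rel)])
    V = ctx.bm_cov(rel)
    res = _gls(np.ones((ctx.n, 1)), x, V)
    if res is None or res[1] <= 0:
        return np.inf, None
    beta, rss, logdet = res
    s = rss / ctx.n
    nll = 0.5 * (ctx.n * math.log(2 * math.pi * s) + logdet + ctx.n)
    return nll, {"scale": s, "rel": rel, "mu": float(beta[0])}


def _fit_bmm(ctx: _LikContext, x: np.ndarray, n_restarts: int,
             rng: np.random.Generator) -> tuple[dict, float, bool]:
    mdim = ctx.m - 1
    starts = [np.zeros(mdim)]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(rng.normal(0.0, 1.5, size=mdim))
    best = None
    ok = False
    for s0 in starts:
        res = optimize.minimize(
            lambda p: _bmm_profile_nll(ctx, x, p)[0], s0,
            method="L-BFGS-B", bounds=[(-25.0, 25.0)] * mdim,
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
            ok = bool(res.success)
        elif res.fun < best.fun + 1e-9:
            ok = ok or bool(res.success)
    _, prof = _bmm_profile_nll(ctx, x, best.x)
    sigma2s = prof["scale"] * prof["rel"]
    params = {"sigma2": {r: float(sigma2s[k]) for k, r in enumerate(ctx.regimes)},
              "mu": prof["mu"]}
    return params, -float(best.fun), ok


def _ou_profile_nll(ctx: _LikContext, x: np.ndarray, alpha: float,
                    model: str, root: str):
    V0 = ctx.ou_cov0(alpha, root)
    X = np.ones((ctx.n, 1)) if model == "OU1" else ctx.ou_design(alpha, root)
    res = _gls(X, x, V0)
    if res is None or res[1] <= 0:
        return np.inf, None
    beta, rss, logdet = res
    s = rss / ctx.n
    nll = 0.5 * (ctx.n * math.log(2 * math.pi * s) + logdet + ctx.n)
    return nll, {"sigma2": s, "beta": beta}


def _fit_ou(ctx: _LikContext, x: np.ndarray, model: str, root: str
            ) -> tuple[dict, float, bool]:
    T = float(ctx.T.max())
    la_lo, la_hi = math.log(ALPHA_MIN), math.log(100.0 / T)
    grid = np.linspace(la_lo, la_hi, 40)
    nlls = np.array([_ou_profile_nll(ctx, x, math.exp(la), model, root)[0]
                     for la in grid])
    j = int(np.argmin(nlls))
    lo = grid[max(0, j - 1)]
    hi = grid[min(len(grid) - 1, j + 1)]
    res = optimize.minimize_scalar(
        lambda la: _ou_profile_nll(ctx, x, math.exp(la), model, root)[0],
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-8},
    )
    la_best = float(res.x) if res.fun <= nlls[j] else float(grid[j])
    nll, prof = _ou_profile_nll(ctx, x, math.exp(la_best), model, root)
    alpha = math.exp(la_best)
    at_boundary = (la_best - la_lo < 1e-6) or (la_hi - la_best < 1e-6)
    params = {"alpha": alpha, "sigma2": float(prof["sigma2"])}
    if model == "OU1":
        params["theta"] = float(prof["beta"][0])
    else:
        params["theta"] = {r: float(prof["beta"][k])
                           for k, r in enumerate(ctx.regimes)}
    return params, -float(nll), not at_boundary


def _model_k(model: str, m: int) -> int:
    return {"BM1": 2, "BMM": m + 1, "OU1": 3, "OUM": m + 2}[model]


def _full_param_vector(model: str, params: dict, regimes) -> np.ndarray:
    if model == "BM1":
        return np.array([math.log(params["sigma2"]), params["mu"]])
    if model == "BMM":
        return np.array([math.log(params["sigma2"][r]) for r in regimes]
                        + [params["mu"]])
    if model == "OU1":
        return np.array([math.log(params["alpha"]),
                         math.log(params["sigma2"]), params["theta"]])
    return np.array([math.log(params["alpha"]), math.log(params["sigma2"])]
                    + [params["theta"][r] for r in regimes])


def _full_nll(model: str, ctx: _LikContext, x: np.ndarray, regimes,
              root: str):
    def nll(p: np.ndarray) -> float:
        try:
            if model == "BM1":
                return -ctx.bm_loglik(x, np.full(ctx.m, math.exp(p[0])), p[1])
            if model == "BMM":
                return -ctx.bm_loglik(x, np.exp(p[:-1]), p[-1])
            alpha = math.exp(p[0])
            sigma2 = math.exp(p[1])
            if model == "OU1":
                thetas = np.full(ctx.m, p[2])
            else:
                thetas = p[2:]
            return -ctx.ou_loglik(x, alpha, sigma2, thetas, root)
        except (linalg.LinAlgError, FloatingPointError, OverflowError):
            return np.inf
    return nll


def _hessian_pd(nll, p: np.ndarray) -> bool:
    """Positive-definiteness of the central-difference Hessian at p."""
    d = len(p)
    h = 1e-4 * np.maximum(1.0, np.abs(p))
    H = np.zeros((d, d))
    f0 = nll(p)
    if not np.isfinite(f0):
        return False
    for i in range(d):
        for j in range(i, d):
            pi, pj = np.zeros(d), np.zeros(d)
            pi[i] = h[i]
            pj[j] = h[j]
            if i == j:
                f = (nll(p + pi) - 2.0 * f0 + nll(p - pi)) / (h[i] ** 2)
            else:
                f = (nll(p + pi + pj) - nll(p + pi - pj)
                     - nll(p - pi + pj) + nll(p - pi - pj)) / (4 * h[i] * h[j])
            H[i, j] = H[j, i] = f
    if not np.all(np.isfinite(H)):
        return False
    eig = np.linalg.eigvalsh(H)
    return bool(eig.min() > 1e-8 * max(1.0, abs(eig.max())))


def fit_model(
    tree: GeneTree,
    traits: TraitTable,
    painting: RegimePainting,
    model: str,
    n_restarts: int = 5,
    seed: int | np.random.Generator | None = None,
    root: str = "fixed",
    check_hessian: bool = True,
) -> ModelFit:
    """Maximum-likelihood fit of one model; see the module docstring.

    The BM mean and the OU optima are profiled out by GLS; the Brownian
    rates use a bounded multi-start quasi-Newton search in log space and the
    OU selection strength a bounded 1-D search over
    log alpha in [log 1e-8, log(100/T)].  Convergence additionally requires
    a positive-definite Hessian of the negative log-likelihood at the
    optimum (in log-rate / log-alpha coordinates).
    """
    if model not in MODEL_NAMES:
        raise ValueError(f"unknown model {model!r}")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    ctx = _LikContext(tree, painting)
    x = ctx.trait_vector(traits)
    if np.ptp(x) == 0.0:
        raise ValueError("trait is invariant across tips")
    n = ctx.n
    k = _model_k(model, ctx.m)
    if n - k - 1 <= 0:
        raise ValueError(f"too few tips (n={n}) for model {model} (k={k})")

    if model == "BM1":
        params, ll = _fit_bm1(ctx, x)
        ok = True
    elif model == "BMM":
        params, ll, ok = _fit_bmm(ctx, x, n_restarts, rng)
    else:
        params, ll, ok = _fit_ou(ctx, x, model, root)

    converged = ok
    message = "" if ok else "optimizer did not converge or hit a bound"
    if ok and check_hessian:
        nll = _full_nll(model, ctx, x, ctx.regimes, root)
        if not _hessian_pd(nll, _full_param_vector(model, params, ctx.regimes)):
            converged = False
            message = "Hessian not positive definite at the optimum"
    return ModelFit(model=model, params=params, loglik=ll, k=k, n=n,
                    aicc=aicc(ll, k, n), converged=converged, message=message)


def select_model(fits: list[ModelFit],
                 tree_id: str | None = None) -> TreeModelReport:
    """Akaike-weight model selection over the convergent fits.

    Weights: w_m = exp(-d_m/2) / sum exp(-d/2) with d_m = AICc_m - min AICc.
    Ties are broken toward fewer parameters, then the fixed model-name
    order BM1, BMM, OU1, OUM.
    """
    usable = [f for f in fits if f.converged and np.isfinite(f.aicc)]
    if not usable:
        return TreeModelReport(tree_id=tree_id, fits=fits,
                               status="all-models-failed")
    a = np.array([f.aicc for f in usable])
    delta = a - a.min()
    w = np.exp(-0.5 * delta)
    w /= w.sum()
    for f, wi in zip(usable, w):
        f.weight = float(wi)
    order = {name: i for i, name in enumerate(MODEL_NAMES)}
    best = min(usable,
               key=lambda f: (f.aicc - a.min() > 1e-9, f.k, order[f.model]))
    return TreeModelReport(tree_id=tree_id, fits=fits, status="ok", best=best)


def fit_all_models(
    tree: GeneTree,
    traits: TraitTable,
    painting: RegimePainting,
    models: tuple[str, ...] = MODEL_NAMES,
    n_restarts: int = 5,
    seed: int | np.random.Generator | None = None,
    root: str = "fixed",
    check_hessian: bool = True,
) -> TreeModelReport:
    """Fit every requested model on one tree and select the best by AICc.

    Multi-regime models are skipped when only one regime is painted (they
    would duplicate their single-regime counterparts), and any model whose
    parameter count leaves no AICc degrees of freedom is dropped for that
    tree.  An invariant trait short-circuits to a "trait-invariant" report.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    x = [traits[t.label] for t in tree.tips if t.label in traits]
    if len(set(x)) <= 1:
        return TreeModelReport(tree_id=tree.tree_id, fits=[],
                               status="trait-invariant")
    fits: list[ModelFit] = []
    for model in models:
        if painting.m == 1 and model in ("BMM", "OUM"):
            continue
        try:
            fits.append(fit_model(tree, traits, painting, model,
                                  n_restarts=n_restarts, seed=rng, root=root,
                                  check_hessian=check_hessian))
        except (ValueError, linalg.LinAlgError):
            continue
    report = select_model(fits, tree_id=tree.tree_id)
    return report
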
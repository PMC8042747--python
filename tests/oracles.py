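"""Independent oracle constructions used to verify the implementation.

Everything here deliberately avoids the package's own computational paths:
covariances are built by brute-force root-path enumeration, contrasts by
successive GLS orthogonalization on the full tip covariance matrix, OU
means by numerical quadrature and OU covariances by numerically integrating
the variance ODE along the shared root path.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate, stats

from paracontrast.gene_trees import GeneTree


def root_path(node):
    """List of nodes from the root (exclusive) down to ``node``."""
    path = []
    while node.parent is not None:
        path.append(node)
        node = node.parent
    return list(reversed(path))


def brute_force_covariance(tree: GeneTree):
    """Tip covariance C by explicit root-path intersection (unit rate)."""
    tips = tree.tips
    paths = {t.id: root_path(t) for t in tips}
    n = len(tips)
    C = np.zeros((n, n))
    for i, a in enumerate(tips):
        for j, b in enumerate(tips):
            ids_b = {nd.id for nd in paths[b.id]}
            C[i, j] = sum(nd.length for nd in paths[a.id] if nd.id in ids_b)
    return C, [t.label for t in tips]


def gls_contrasts(tree: GeneTree, traits) -> dict[int, tuple[float, float]]:
    """Contrasts by successive GLS orthogonalization on the covariance matrix.

    Processes internal nodes in postorder; at each node the two current
    representatives of its child subtrees are differenced and replaced by
    their GLS-optimal combination, updating the covariance matrix by the
    corresponding linear map.  Returns {node_id: (contrast, expected_sd)}.
    """
    C, labels = brute_force_covariance(tree)
    values = [traits[lab] for lab in labels]
    rep = {t.id: k for k, t in enumerate(tree.tips)}  # node -> active index
    active = list(range(len(labels)))
    out = {}
    for node in tree.postorder():
        if node.is_tip:
            continue
        ia = rep[node.children[0].id]
        ib = rep[node.children[1].id]
        var = C[ia, ia] + C[ib, ib] - 2.0 * C[ia, ib]
        sd = math.sqrt(var)
        u = (values[ia] - values[ib]) / sd
        out[node.id] = (u, sd)
        # GLS merge: weight minimizing the variance of the combination
        a = (C[ib, ib] - C[ia, ib]) / var
        merged = a * values[ia] + (1 - a) * values[ib]
        newcov = a * C[ia, :] + (1 - a) * C[ib, :]
        newvar = (a * a * C[ia, ia] + (1 - a) * (1 - a) * C[ib, ib]
                  + 2 * a * (1 - a) * C[ia, ib])
        C[ia, :] = newcov
        C[:, ia] = newcov
        C[ia, ia] = newvar
        values[ia] = merged
        rep[node.id] = ia
    return out


def bm_dense_loglik(tree: GeneTree, traits, painting, rates, mu) -> float:
    """BM log-likelihood from an explicitly assembled covariance matrix."""
    tips = tree.tips
    paths = {t.id: root_path(t) for t in tips}
    n = len(tips)
    V = np.zeros((n, n))
    for i, a in enumerate(tips):
        for j, b in enumerate(tips):
            ids_b = {nd.id for nd in paths[b.id]}
            V[i, j] = sum(
                rates[painting.branch_states[nd.id]] * nd.length
                for nd in paths[a.id] if nd.id in ids_b
            )
    x = np.array([traits[t.label] for t in tips])
    return float(stats.multivariate_normal.logpdf(x, mean=np.full(n, mu),
                                                  cov=V))


def ou_dense_loglik(tree: GeneTree, traits, painting, alpha, sigma2, thetas,
                    root="fixed") -> float:
    """OU log-likelihood from quadrature means and ODE-integrated covariances.

    The mean integrates alpha * e^{-alpha (T_i - t)} * theta(t) numerically
    along each tip's root path; the covariance integrates the variance ODE
    v' = -2 alpha v + sigma^2 along the shared path and discounts by
    e^{-alpha (residual path)} on both sides.
    """
    tips = tree.tips
    heights = tree.heights()
    paths = {t.id: root_path(t) for t in tips}
    n = len(tips)
    root_theta = thetas[painting.root_regime]

    def mean_for(tip):
        Ti = heights[tip.id]
        total = math.exp(-alpha * Ti) * root_theta
        for nd in paths[tip.id]:
            h0 = heights[nd.parent.id]
            h1 = heights[nd.id]
            th = thetas[painting.branch_states[nd.id]]
            val, _ = integrate.quad(
                lambda t: alpha * math.exp(-alpha * (Ti - t)) * th, h0, h1)
            total += val
        return total

    def shared_time(a, b):
        ids_b = {nd.id for nd in paths[b.id]}
        shared = [nd for nd in paths[a.id] if nd.id in ids_b]
        return sum(nd.length for nd in shared)

    V = np.zeros((n, n))
    for i, a in enumerate(tips):
        for j, b in enumerate(tips):
            t_sh = shared_time(a, b)
            v0 = sigma2 / (2 * alpha) if root == "stationary" else 0.0
            sol = integrate.solve_ivp(
                lambda t, v: -2 * alpha * v + sigma2, (0.0, max(t_sh, 1e-12)),
                [v0], rtol=1e-10, atol=1e-14)
            v_mrca = sol.y[0, -1] if t_sh > 0 else v0
            resid = (heights[a.id] - t_sh) + (heights[b.id] - t_sh)
            V[i, j] = v_mrca * math.exp(-alpha * resid)
    x = np.array([traits[t.label] for t in tips])
    mean = np.array([mean_for(t) for t in tips])
    return float(stats.multivariate_normal.logpdf(x, mean=mean, cov=V))


def blomberg_k_matrix_oracle(C: np.ndarray, x: np.ndarray) -> float:
    """K from its defining variance ratios, written directly from C."""
    n = len(x)
    Cinv = np.linalg.inv(C)
    ones = np.ones(n)
    a_hat = (ones @ Cinv @ x) / (ones @ Cinv @ ones)
    r = x - a_hat
    mse0 = (r @ r) / (n - 1)
    mse = (r @ Cinv @ r) / (n - 1)
    expected = (np.trace(C) - n / (ones @ Cinv @ ones)) / (n - 1)
    return float((mse0 / mse) / expected)
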
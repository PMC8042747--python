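"""Hypothesis layer: speciation-vs-duplication comparisons and the three
bias-corrected analysis pipelines.

The ortholog conjecture predicts faster trait evolution after gene
duplication than after speciation.  On contrasts this is tested by a
Wilcoxon rank-sum comparison of |PIC| at duplication vs speciation nodes
(one-sided: duplication > speciation; the two-sided version detects the
calibration-driven pseudosignal in the opposite direction).  Three
safeguards against branch-length and model biases are provided:

* approach 1 — only trees passing the four contrast-standardization
  diagnostics contribute contrasts, analysed separately for young and old
  duplications;
* approach 2 — branch lengths are power-transformed per tree until
  contrasts standardize, then pooled (no young/old split: the transformed
  trees have no absolute time scale);
* approach 3 — per-tree BM/OU model selection; rates sigma^2 are compared
  between regimes on trees best fitted by multi-rate BM, optima theta on
  trees best fitted by multi-optimum OU, with paired Wilcoxon tests.

Randomization studies re-run any of these analyses on tip-trait or
node-event permutations of the data to check that an empirical trend is not
an artefact of the tree structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .gene_trees import (Event, GeneTree, TraitTable,
                         classify_duplication_ages, max_speciation_age)
from .contrasts import (ContrastRecord, TransformResult, compute_pic,
                        diagnostics, transform_branch_lengths)
from .trait_models import (Regime, TreeModelReport, fit_all_models, fit_model,
                           paint_regimes, select_model)
from .synthetic_data import permute_node_events, permute_tip_traits

__all__ = [
    "OCTestResult",
    "ModelComparisonResult",
    "Approach1Result",
    "Approach2Result",
    "Approach3Result",
    "RandomizationStudy",
    "oc_test",
    "pooled_contrasts",
    "run_naive_pic",
    "run_approach1",
    "run_approach2",
    "run_approach3",
    "run_randomization_study",
]


@dataclass
class OCTestResult:
    """Wilcoxon rank-sum comparison of |contrast| between node events."""

    stratum: str  # "pooled" | "young" | "old"
    n_speciation: int
    n_duplication: int
    median_speciation: float  # medians of |contrast|
    median_duplication: float
    median_speciation_raw: float  # medians of signed contrasts
    median_duplication_raw: float
    statistic: float
    p_one_sided: float  # H1: duplication > speciation
    p_two_sided: float
    evaluable: bool = True

    @property
    def supports_conjecture(self) -> bool:
        return self.evaluable and self.p_one_sided < 0.05


@dataclass
class ModelComparisonResult:
    """Paired per-tree comparison of sigma^2 (BMM trees) or theta (OUM)."""

    quantity: str  # "sigma2" | "theta"
    stratum: str  # "young" | "old"
    n_trees: int
    values_speciation: list[float]
    values_duplication: list[float]
    median_speciation: float
    median_duplication: float
    p_two_sided: float
    evaluable: bool = True


@dataclass
class Approach1Result:
    young: OCTestResult
    old: OCTestResult
    gating: list[tuple[str, bool, list[str]]]  # tree_id, passed, failed tests
    n_passed: int
    n_trees: int


@dataclass
class Approach2Result:
    pooled: OCTestResult
    transforms: dict[str, TransformResult]
    n_passed: int
    n_trees: int


@dataclass
class Approach3Result:
    reports: dict[str, TreeModelReport]
    census: dict[str, int]  # best-model name -> count
    sigma2: dict[str, ModelComparisonResult]  # stratum -> result
    theta: dict[str, ModelComparisonResult]
    n_invariant: int


@dataclass
class RandomizationStudy:
    mode: str  # "tip-traits" | "node-events"
    analysis: str
    n_reps: int
    seeds: list[int]
    results: list  # per-replicate analysis results
    p_values: list[float]  # the headline p per replicate


# ---------------------------------------------------------------------------
# rank-sum comparison
# ---------------------------------------------------------------------------

def oc_test(records: list[ContrastRecord], stratum: str = "pooled",
            exact_max_n: int = 50) -> OCTestResult:
    """Compare |contrast| of duplication vs speciation nodes.

    ``stratum`` selects duplication contrasts: "young"/"old" keep only
    duplications of that age class (speciation contrasts are always shared
    across strata); "pooled" keeps all.  NA-event contrasts never enter.
    The exact rank-sum null is used when both groups have at most
    ``exact_max_n`` observations and no ties; otherwise the tie-corrected
    normal approximation.
    """
    spe = [r.abs_contrast for r in records if r.event is Event.SPECIATION]
    spe_raw = [r.contrast for r in records if r.event is Event.SPECIATION]
    dups = [r for r in records if r.event is Event.DUPLICATION]
    if stratum in ("young", "old"):
        dups = [r for r in dups if r.age_class == stratum]
    elif stratum != "pooled":
        raise ValueError(f"unknown stratum {stratum!r}")
    dup = [r.abs_contrast for r in dups]
    dup_raw = [r.contrast for r in dups]
    if not spe or not dup:
        return OCTestResult(stratum=stratum, n_speciation=len(spe),
                            n_duplication=len(dup),
                            median_speciation=float("nan"),
                            median_duplication=float("nan"),
                            median_speciation_raw=float("nan"),
                            median_duplication_raw=float("nan"),
                            statistic=float("nan"), p_one_sided=float("nan"),
                            p_two_sided=float("nan"), evaluable=False)
    method = "exact" if (len(spe) <= exact_max_n and len(dup) <= exact_max_n
                         and len(set(spe + dup)) == len(spe) + len(dup)) \
        else "asymptotic"
    one = stats.mannwhitneyu(dup, spe, alternative="greater", method=method)
    two = stats.mannwhitneyu(dup, spe, alternative="two-sided", method=method)
    return OCTestResult(
        stratum=stratum, n_speciation=len(spe), n_duplication=len(dup),
        median_speciation=float(np.median(spe)),
        median_duplication=float(np.median(dup)),
        median_speciation_raw=float(np.median(spe_raw)),
        median_duplication_raw=float(np.median(dup_raw)),
        statistic=float(one.statistic),
        p_one_sided=float(one.pvalue), p_two_sided=float(two.pvalue),
    )


# ---------------------------------------------------------------------------
# pipelines
# ---------------------------------------------------------------------------

def _resolve_threshold(trees, age_threshold):
    if age_threshold == "auto":
        return max_speciation_age(trees)
    return float(age_threshold)


def pooled_contrasts(
    trees: list[GeneTree],
    traits: dict[str, TraitTable],
    age_threshold: float | str = "auto",
) -> list[ContrastRecord]:
    """All contrasts of a tree set, with duplication age classes attached."""
    threshold = _resolve_threshold(trees, age_threshold)
    records: list[ContrastRecord] = []
    for tree in trees:
        classes = classify_duplication_ages([tree], threshold)[tree.tree_id]
        records.extend(compute_pic(tree, traits[tree.tree_id],
                                   age_classes=classes))
    return records


def run_naive_pic(
    trees: list[GeneTree],
    traits: dict[str, TraitTable],
    age_threshold: float | str = "auto",
) -> OCTestResult:
    """Straightforward pooled PIC comparison with no diagnostics gating —
    the analysis whose biases the corrected approaches address."""
    return oc_test(pooled_contrasts(trees, traits, age_threshold), "pooled")


def run_approach1(
    trees: list[GeneTree],
    traits: dict[str, TraitTable],
    alpha: float = 0.05,
    age_threshold: float | str = "auto",
) -> Approach1Result:
    """PIC restricted to trees passing the four diagnostic tests, with the
    duplication contrasts split into young and old strata."""
    threshold = _resolve_threshold(trees, age_threshold)
    gating: list[tuple[str, bool, list[str]]] = []
    pool: list[ContrastRecord] = []
    for tree in trees:
        classes = classify_duplication_ages([tree], threshold)[tree.tree_id]
        records = compute_pic(tree, traits[tree.tree_id], age_classes=classes)
        diag = diagnostics(records, alpha=alpha)
        failed = [] if not diag.evaluable else \
            [t.predictor for t in diag.tests if not t.passed]
        passed = diag.passed
        gating.append((tree.tree_id, passed, failed))
        if passed:
            pool.extend(records)
    return Approach1Result(
        young=oc_test(pool, "young"),
        old=oc_test(pool, "old"),
        gating=gating,
        n_passed=sum(1 for _, ok, _ in gating if ok),
        n_trees=len(trees),
    )


def run_approach2(
    trees: list[GeneTree],
    traits: dict[str, TraitTable],
    alpha: float = 0.05,
) -> Approach2Result:
    """Per-tree branch-length transformation, four-test gating on the
    transformed trees, then a pooled comparison (no young/old split — the
    transformed branch lengths carry no absolute age)."""
    transforms: dict[str, TransformResult] = {}
    pool: list[ContrastRecord] = []
    n_passed = 0
    for tree in trees:
        tr = transform_branch_lengths(tree, traits[tree.tree_id], alpha=alpha)
        transforms[tree.tree_id] = tr
        if tr.excluded or tr.diagnostics is None or not tr.diagnostics.passed:
            continue
        n_passed += 1
        pool.extend(compute_pic(tr.transformed_tree, traits[tree.tree_id]))
    return Approach2Result(pooled=oc_test(pool, "pooled"),
                           transforms=transforms, n_passed=n_passed,
                           n_trees=len(trees))


def _paired_comparison(pairs_by_stratum, quantity: str) -> dict:
    out = {}
    for stratum, pairs in pairs_by_stratum.items():
        spe = [a for a, _ in pairs]
        dup = [b for _, b in pairs]
        if len(pairs) >= 2 and any(a != b for a, b in pairs):
            p = float(stats.wilcoxon(dup, spe).pvalue)
            ok = True
        else:
            p = float("nan")
            ok = False
        out[stratum] = ModelComparisonResult(
            quantity=quantity, stratum=stratum, n_trees=len(pairs),
            values_speciation=spe, values_duplication=dup,
            median_speciation=float(np.median(spe)) if spe else float("nan"),
            median_duplication=float(np.median(dup)) if dup else float("nan"),
            p_two_sided=p, evaluable=ok,
        )
    return out


def run_approach3(
    trees: list[GeneTree],
    traits: dict[str, TraitTable],
    age_threshold: float | str = "auto",
    n_restarts: int = 5,
    seed: int | None = 0,
    check_hessian: bool = True,
) -> Approach3Result:
    """Per-tree model selection and regime-parameter comparisons.

    sigma^2 is compared between the speciation and duplication regimes over
    trees whose best model is BMM; theta over trees whose best model is
    OUM; each paired per tree, split by duplication age class, tested with
    the two-sided Wilcoxon signed-rank test.
    """
    threshold = _resolve_threshold(trees, age_threshold)
    ss = np.random.SeedSequence(seed)
    reports: dict[str, TreeModelReport] = {}
    census: dict[str, int] = {}
    n_invariant = 0
    sigma_pairs = {"young": [], "old": []}
    theta_pairs = {"young": [], "old": []}
    for tree, child in zip(trees, ss.spawn(len(trees))):
        painting = paint_regimes(tree, age_threshold=threshold)
        report = fit_all_models(tree, traits[tree.tree_id], painting,
                                n_restarts=n_restarts,
                                seed=np.random.default_rng(child),
                                check_hessian=check_hessian)
        reports[tree.tree_id] = report
        if report.status == "trait-invariant":
            n_invariant += 1
            continue
        if report.status != "ok":
            continue
        best = report.best
        census[best.model] = census.get(best.model, 0) + 1
        if best.model == "BMM":
            by_regime = best.params["sigma2"]
            _collect_pairs(by_regime, sigma_pairs)
        elif best.model == "OUM":
            _collect_pairs(best.params["theta"], theta_pairs)
    return Approach3Result(
        reports=reports, census=census,
        sigma2=_paired_comparison(sigma_pairs, "sigma2"),
        theta=_paired_comparison(theta_pairs, "theta"),
        n_invariant=n_invariant,
    )


def _collect_pairs(by_regime: dict, pairs: dict) -> None:
    if Regime.SPECIATION not in by_regime:
        return
    spe = by_regime[Regime.SPECIATION]
    if Regime.DUP_YOUNG in by_regime:
        pairs["young"].append((spe, by_regime[Regime.DUP_YOUNG]))
    if Regime.DUP_OLD in by_regime:
        pairs["old"].append((spe, by_regime[Regime.DUP_OLD]))


# ---------------------------------------------------------------------------
# randomization studies
# ---------------------------------------------------------------------------

_ANALYSES = ("naive-PIC", "approach1", "approach2", "approach3")


def run_randomization_study(
    trees: list[GeneTree],
    traits: dict[str, TraitTable],
    mode: str = "tip-traits",
    n_reps: int = 100,
    analysis: str = "naive-PIC",
    seed: int | None = 0,
    age_threshold: float | str = "auto",
    alpha: float = 0.05,
    baseline: Approach3Result | None = None,
) -> RandomizationStudy:
    """Re-run an analysis on ``n_reps`` independent permutations of the data.

    ``mode`` "tip-traits" permutes trait values over each tree's tips,
    keeping node events; "node-events" permutes internal-node events (and
    re-derives young/old classes), keeping traits.  Under "approach3" the
    best model per tree is frozen from the unrandomized run (supplied as
    ``baseline`` or computed here) and only its parameters are re-estimated.
    Each replicate's seed is recorded for reproducibility.
    """
    if mode not in ("tip-traits", "node-events"):
        raise ValueError(f"unknown randomization mode {mode!r}")
    if analysis not in _ANALYSES:
        raise ValueError(f"unknown analysis {analysis!r}")
    threshold = _resolve_threshold(trees, age_threshold)
    if analysis == "approach3" and baseline is None:
        baseline = run_approach3(trees, traits, age_threshold=threshold,
                                 seed=seed)
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
                 ss.spawn(n_reps)]
    results = []
    p_values = []
    for rep_seed in rep_seeds:
        rng = np.random.default_rng(rep_seed)
        if mode == "tip-traits":
            rep_trees = trees
            rep_traits = {t.tree_id: permute_tip_traits(t, traits[t.tree_id],
                                                        seed=rng)
                          for t in trees}
        else:
            rep_trees = [permute_node_events(t, seed=rng) for t in trees]
            rep_traits = traits
        if analysis == "naive-PIC":
            res = run_naive_pic(rep_trees, rep_traits, threshold)
            p = res.p_two_sided
        elif analysis == "approach1":
            res = run_approach1(rep_trees, rep_traits, alpha=alpha,
                                age_threshold=threshold)
            p = res.young.p_one_sided
        elif analysis == "approach2":
            res = run_approach2(rep_trees, rep_traits, alpha=alpha)
            p = res.pooled.p_one_sided
        else:
            res = _refit_frozen(rep_trees, rep_traits, baseline, threshold,
                                rng)
            p = res["sigma2"]["young"].p_two_sided if res["sigma2"] else \
                float("nan")
        results.append(res)
        p_values.append(float(p))
    return RandomizationStudy(mode=mode, analysis=analysis, n_reps=n_reps,
                              seeds=rep_seeds, results=results,
                              p_values=p_values)


def _refit_frozen(trees, traits, baseline: Approach3Result, threshold, rng):
    """Re-estimate only each tree's frozen best model on randomized data."""
    sigma_pairs = {"young": [], "old": []}
    theta_pairs = {"young": [], "old": []}
    for tree in trees:
        report = baseline.reports.get(tree.tree_id)
        if report is None or report.status != "ok":
            continue
        painting = paint_regimes(tree, age_threshold=threshold)
        try:
            fit = fit_model(tree, traits[tree.tree_id], painting,
                            report.best.model, seed=rng,
                            check_hessian=False)
        except Exception:
            continue
        if fit.model == "BMM":
            _collect_pairs(fit.params["sigma2"], sigma_pairs)
        elif fit.model == "OUM":
            _collect_pairs(fit.params["theta"], theta_pairs)
    return {"sigma2": _paired_comparison(sigma_pairs, "sigma2"),
            "theta": _paired_comparison(theta_pairs, "theta")}
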
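"""Models of incompatibility accumulation on the three-taxon tree.

Generative model
----------------
Substitutions arrive as a Poisson process with constant rate along
branches of the ultrametric tree (clock enforced).  Each substitution on a
donor-lineage branch (b, c or d) participates in an observable
incompatibility against the SL background with a probability proportional
to the number of potential deleterious interactions available to it — the
small-probability ("weak mutation, weak incompatibility") regime, in which
the per-branch counts of DMI-participating mutations are independent
Poisson variables.  Only composite rate x probability products are
identifiable in this regime, which fixes the parameter counts below.

With depth ``T``, branch b spanning the depth interval [0, t_b] and each
terminal branch [t_b, T], the expected counts are closed-form integrals of
a per-substitution weight over the branch:

* ``linear`` (1 parameter, rho): weight 1 — mutations land in proportion
  to branch length, no epistasis.  mu_x = rho * t_x.
* ``DM`` (1 parameter, c): pairwise snowball.  A substitution at depth u
  has T derived-derived partner-budget (the whole SL lineage) plus u
  derived-ancestral partners (its own lineage's earlier substitutions), so
  mu_x = c * (T * t_x + (u1^2 - u0^2)/2).
* ``paPd`` (2 parameters, c_d and c_a): as DM but derived-derived and
  derived-ancestral interactions weighted separately:
  mu_x = c_d * T * t_x + c_a * (u1^2 - u0^2)/2.
* ``p2p3`` (2 parameters, c2 and c3): the DM pairwise term plus a
  three-locus term c3 * M3_x, where M3_x is the Monte-Carlo expectation of
  per-focal three-locus interaction counts (ddd + dda) summed over the
  focal substitutions on branch x, under unit-rate Poisson substitution
  histories along the full root-to-tip lineage path.

Fitting maximizes the independent-Poisson log likelihood of the observed
(n_b, n_c, n_d) per tree; models are compared by AIC = 2k - 2 loglik,
averaged over a tree set to propagate phylogenetic uncertainty.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.special import gammaln

from .combinatorics import per_focal_new_triples
from .placement import BranchCounts
from .tables import RunConfig
from .trees import ThreeTaxonTree, TreeSet

logger = logging.getLogger(__name__)

MODEL_NAMES = ("linear", "DM", "p2p3", "paPd")
MODEL_PARAM_NAMES = {
    "linear": ("rho",),
    "DM": ("c",),
    "p2p3": ("c2", "c3"),
    "paPd": ("c_d", "c_a"),
}
#: fixed tie-break order for AIC model selection
MODEL_ORDER = {name: i for i, name in enumerate(MODEL_NAMES)}


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    name: str
    params: dict[str, float]

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ModelError(f"unknown model {self.name!r}")
        expected = MODEL_PARAM_NAMES[self.name]
        if tuple(self.params) != expected:
            raise ModelError(
                f"model {self.name} takes parameters {expected}, got {tuple(self.params)}"
            )
        for key, value in self.params.items():
            if not math.isfinite(value) or value < 0:
                raise ModelError(f"parameter {key}={value!r} must be finite and >= 0")

    @property
    def k(self) -> int:
        return len(self.params)

    def values(self) -> np.ndarray:
        return np.array(list(self.params.values()), dtype=float)

    def with_values(self, values: Sequence[float]) -> "ModelSpec":
        return replace(
            self, params=dict(zip(MODEL_PARAM_NAMES[self.name], map(float, values)))
        )


def make_model(name: str, *values: float) -> ModelSpec:
    names = MODEL_PARAM_NAMES[name]
    if len(values) != len(names):
        raise ModelError(f"model {name} takes {len(names)} parameter(s)")
    return ModelSpec(name=name, params=dict(zip(names, map(float, values))))


@dataclass(frozen=True)
class ExpectedCounts:
    mu_b: float
    mu_c: float
    mu_d: float

    @property
    def total(self) -> float:
        return self.mu_b + self.mu_c + self.mu_d

    def as_array(self) -> np.ndarray:
        return np.array([self.mu_b, self.mu_c, self.mu_d], dtype=float)


# ---------------------------------------------------------------------------
# per-branch basis functions (mu is linear in the composite parameters)
# ---------------------------------------------------------------------------

def _branch_intervals(tree: ThreeTaxonTree) -> dict[str, tuple[float, float]]:
    T = tree.depth_T
    return {"b": (0.0, tree.t_b), "c": (tree.t_b, T), "d": (tree.t_b, T)}


def _require_clock(tree: ThreeTaxonTree) -> None:
    if not tree.ultrametric:
        raise ModelError("expected_counts needs an ultrametric tree; run enforce_clock")


def dd_basis(tree: ThreeTaxonTree) -> np.ndarray:
    """Integral of the derived-derived partner budget T over each branch."""
    _require_clock(tree)
    T = tree.depth_T
    return np.array([T * tree.t_b, T * tree.t_c, T * tree.t_d])


def da_basis(tree: ThreeTaxonTree) -> np.ndarray:
    """Integral of the derived-ancestral budget u over each branch:
    (u1^2 - u0^2) / 2."""
    _require_clock(tree)
    out = []
    for branch in ("b", "c", "d"):
        u0, u1 = _branch_intervals(tree)[branch]
        out.append((u1**2 - u0**2) / 2.0)
    return np.array(out)


def linear_basis(tree: ThreeTaxonTree) -> np.ndarray:
    _require_clock(tree)
    return np.array([tree.t_b, tree.t_c, tree.t_d])


# ---------------------------------------------------------------------------
# Monte-Carlo three-locus term (depends on the tree only; cached per call
# site via triple_basis)
# ---------------------------------------------------------------------------

def triple_mc_basis(
    tree: ThreeTaxonTree, mc_reps: int = 20000, seed: int = 0
) -> np.ndarray:
    """M3_x for x in (b, c, d): expected number of three-locus interactions
    completed by substitutions on branch x.

    Each replicate draws a unit-rate Poisson substitution history along the
    full root-to-tip lineage path through the branch (length T; for the
    shared branch b the path runs through a terminal, symmetric under the
    clock) and an independent SL-lineage count K_other ~ Poisson(t_a).
    Arrival depths are uniform given the count; the temporal order index of
    each substitution is its depth rank.  Focal substitutions are those
    whose depth falls inside the branch's interval; each contributes the
    trios it completes (see :func:`per_focal_new_triples`), so every trio
    is attributed to exactly one branch.
    """
    _require_clock(tree)
    rng = np.random.default_rng(seed)
    T = tree.depth_T
    intervals = _branch_intervals(tree)
    totals = {b: 0.0 for b in ("b", "c", "d")}
    k1 = rng.poisson(T, size=mc_reps)
    k2 = rng.poisson(tree.t_a, size=mc_reps)
    for K1, K2 in zip(k1, k2):
        if K1 < 2:
            # three-locus interactions need two same-lineage substitutions
            continue
        depths = np.sort(rng.uniform(0.0, T, size=K1))
        per_focal = np.array(
            [per_focal_new_triples(i, K2) for i in range(1, K1 + 1)], dtype=float
        )
        for branch, (u0, u1) in intervals.items():
            mask = (depths > u0) & (depths <= u1) if u0 > 0 else (depths <= u1)
            totals[branch] += float(per_focal[mask].sum())
    return np.array([totals["b"] / mc_reps, totals["c"] / mc_reps, totals["d"] / mc_reps])


class BasisCache:
    """Per-tree design matrices; M3 is the only expensive column."""

    def __init__(self, config: Optional[RunConfig] = None):
        self.config = config or RunConfig()
        self._cache: dict[tuple, dict[str, np.ndarray]] = {}

    def get(self, tree: ThreeTaxonTree, need_triples: bool = False) -> dict[str, np.ndarray]:
        key = (round(tree.t_a, 12), round(tree.t_b, 12), round(tree.t_c, 12), round(tree.t_d, 12))
        entry = self._cache.setdefault(key, {})
        if "linear" not in entry:
            entry["linear"] = linear_basis(tree)
            entry["dd"] = dd_basis(tree)
            entry["da"] = da_basis(tree)
        if need_triples and "m3" not in entry:
            entry["m3"] = triple_mc_basis(
                tree, mc_reps=self.config.mc_reps, seed=self.config.seed
            )
        return entry


def model_design(
    model_name: str, tree: ThreeTaxonTree, basis: Optional[dict[str, np.ndarray]] = None,
    config: Optional[RunConfig] = None,
) -> np.ndarray:
    """3 x k matrix B with mu = B @ params (mu is linear in the composites)."""
    if basis is None:
        basis = BasisCache(config).get(tree, need_triples=model_name == "p2p3")
    if model_name == "linear":
        return basis["linear"][:, None]
    if model_name == "DM":
        return (basis["dd"] + basis["da"])[:, None]
    if model_name == "p2p3":
        return np.column_stack([basis["dd"] + basis["da"], basis["m3"]])
    if model_name == "paPd":
        return np.column_stack([basis["dd"], basis["da"]])
    raise ModelError(f"unknown model {model_name!r}")


def expected_counts(
    model: ModelSpec,
    tree: ThreeTaxonTree,
    config: Optional[RunConfig] = None,
    basis_cache: Optional["BasisCache"] = None,
) -> ExpectedCounts:
    """Expected per-branch counts of DMI-participating mutations."""
    basis = None
    if basis_cache is not None:
        basis = basis_cache.get(tree, need_triples=model.name == "p2p3")
    design = model_design(model.name, tree, basis=basis, config=config)
    mu = design @ model.values()
    return ExpectedCounts(*map(float, mu))


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _poisson_loglik(n: np.ndarray, mu: np.ndarray) -> float:
    n = np.asarray(n, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any((mu <= 0) & (n > 0)):
        return -np.inf
    safe = mu > 0
    ll = float(np.sum(n[safe] * np.log(mu[safe]) - mu[safe] - gammaln(n[safe] + 1)))
    ll -= float(np.sum(mu[~safe]))  # zero-mean branches contribute only -mu (=0)
    return ll


def loglik(
    model: ModelSpec,
    counts: BranchCounts,
    tree: ThreeTaxonTree,
    config: Optional[RunConfig] = None,
) -> float:
    """Independent-Poisson log likelihood of (n_b, n_c, n_d).

    Returns -inf (with a log warning) when a branch with observed
    mutations has zero expected count under the model.
    """
    mu = expected_counts(model, tree, config=config).as_array()
    n = np.array(counts.as_tuple(), dtype=float)
    ll = _poisson_loglik(n, mu)
    if ll == -np.inf:
        logger.warning("model %s puts zero mass on an observed branch", model.name)
    return ll


def loglik_total_multinomial(
    model: ModelSpec,
    counts: BranchCounts,
    tree: ThreeTaxonTree,
    config: Optional[RunConfig] = None,
) -> float:
    """Equivalent factorization: Poisson total x multinomial split.

    The joint distribution of the per-pair totals with a shared internal
    branch factorizes as the total count N ~ Poisson(sum mu) times a
    multinomial allocation with probabilities mu / sum mu.  Numerically
    identical to :func:`loglik`; kept as an independent cross-check of the
    likelihood algebra.
    """
    mu = expected_counts(model, tree, config=config).as_array()
    n = np.array(counts.as_tuple(), dtype=float)
    if np.any((mu <= 0) & (n > 0)):
        return -np.inf
    total_mu = mu.sum()
    N = n.sum()
    if total_mu == 0:
        return 0.0 if N == 0 else -np.inf
    ll = N * math.log(total_mu) - total_mu - float(gammaln(N + 1))  # Poisson(N)
    safe = mu > 0
    ll += float(gammaln(N + 1) - np.sum(gammaln(n[safe] + 1)))
    ll += float(np.sum(n[safe] * (np.log(mu[safe]) - math.log(total_mu))))
    return ll


# ---------------------------------------------------------------------------
# fitting and model comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelFit:
    model: ModelSpec
    loglik: float
    aic: float
    aic_sd: float
    n_trees: int
    per_tree_aic: tuple[float, ...] = ()


def _fit_single_tree(
    name: str, n: np.ndarray, design: np.ndarray, seed: int, n_starts: int = 5
) -> tuple[np.ndarray, float]:
    """Maximize the Poisson log likelihood over nonnegative composites.

    mu = design @ theta is linear in theta, so the log likelihood is
    concave; bounded L-BFGS-B from a few seeded starts is ample.
    """
    k = design.shape[1]
    rng = np.random.default_rng(seed)
    total_n = max(n.sum(), 1.0)
    col_tot = design.sum(axis=0)
    col_tot[col_tot == 0] = 1.0
    base = total_n / (k * col_tot)  # moment-matched start

    def neg_ll(theta: np.ndarray) -> float:
        return -_poisson_loglik(n, design @ theta)

    best_theta, best_val = None, np.inf
    starts = [base] + [base * rng.uniform(0.2, 5.0, size=k) for _ in range(n_starts - 1)]
    for x0 in starts:
        res = optimize.minimize(
            neg_ll,
            np.maximum(x0, 1e-12),
            method="L-BFGS-B",
            bounds=[(0.0, None)] * k,
            options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500},
        )
        if res.fun < best_val:
            best_val, best_theta = res.fun, res.x
    if best_theta is None or not np.isfinite(best_val):
        raise ModelError(f"optimizer failed to converge for model {name}")
    return best_theta, -best_val


def fit_model(
    name: str,
    counts: BranchCounts,
    trees: TreeSet | ThreeTaxonTree,
    config: Optional[RunConfig] = None,
    basis_cache: Optional[BasisCache] = None,
) -> ModelFit:
    """Fit one accumulation model by ML on every tree; average the AIC.

    Reported parameter estimates come from the tree with the median AIC;
    ``aic``/``aic_sd`` are the mean and SD over trees (SD = 0 for a single
    tree).  Trees on which the optimizer fails are skipped with a warning.
    """
    if isinstance(trees, ThreeTaxonTree):
        trees = TreeSet(trees=(trees,), source_label="single")
    config = config or RunConfig()
    cache = basis_cache or BasisCache(config)
    n = np.array(counts.as_tuple(), dtype=float)
    k = len(MODEL_PARAM_NAMES[name])
    results: list[tuple[float, float, np.ndarray]] = []  # (aic, ll, theta)
    for tree_idx, tree in enumerate(trees):
        tree = tree if tree.ultrametric else _clocked(tree)
        basis = cache.get(tree, need_triples=name == "p2p3")
        design = model_design(name, tree, basis=basis)
        try:
            theta, ll = _fit_single_tree(name, n, design, seed=config.seed + tree_idx)
        except ModelError:
            logger.warning("skipping tree %d: optimizer failure for %s", tree_idx, name)
            continue
        results.append((2 * k - 2 * ll, ll, theta))
    if not results:
        raise ModelError(f"model {name}: optimizer failed on every tree")
    aics = np.array([r[0] for r in results])
    median_idx = int(np.argsort(aics)[len(aics) // 2])
    aic_med, ll_med, theta_med = results[median_idx]
    return ModelFit(
        model=make_model(name, *theta_med),
        loglik=ll_med,
        aic=float(aics.mean()),
        aic_sd=float(aics.std(ddof=0)) if len(aics) > 1 else 0.0,
        n_trees=len(results),
        per_tree_aic=tuple(map(float, aics)),
    )


def _clocked(tree: ThreeTaxonTree) -> ThreeTaxonTree:
    from .trees import enforce_clock

    return enforce_clock(tree)


@dataclass(frozen=True)
class ModelComparison:
    fits: dict[str, ModelFit]
    selected: str

    def table(self):
        import pandas as pd

        rows = []
        for name in MODEL_NAMES:
            fit = self.fits[name]
            rows.append(
                {
                    "model": name,
                    "k": fit.model.k,
                    "loglik": fit.loglik,
                    "aic_mean": fit.aic,
                    "aic_sd": fit.aic_sd,
                    "n_trees": fit.n_trees,
                    "selected": name == self.selected,
                    **{f"param_{p}": v for p, v in fit.model.params.items()},
                }
            )
        return pd.DataFrame(rows)


def compare_models(
    counts: BranchCounts,
    trees: TreeSet | ThreeTaxonTree,
    config: Optional[RunConfig] = None,
    model_names: Sequence[str] = MODEL_NAMES,
    basis_cache: Optional[BasisCache] = None,
) -> ModelComparison:
    """Fit all models and select by minimum mean AIC.

    Ties break toward fewer parameters, then the fixed order
    linear < DM < p2p3 < paPd.
    """
    config = config or RunConfig()
    cache = basis_cache or BasisCache(config)
    fits = {
        name: fit_model(name, counts, trees, config=config, basis_cache=cache)
        for name in model_names
    }
    selected = min(
        fits, key=lambda m: (fits[m].aic, fits[m].model.k, MODEL_ORDER[m])
    )
    return ModelComparison(fits=fits, selected=selected)
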
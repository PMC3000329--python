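"""Strict-molecular-clock machinery under HKY85.

* :func:`hky_loglik` — pruning (Felsenstein) log-likelihood with the
  analytic HKY85 transition probabilities;
* :func:`clock_lrt` — likelihood-ratio test of rate homogeneity: free
  branch lengths versus an ultrametric (clock) tree, chi-square with
  n - 2 degrees of freedom for n tips;
* :func:`mcmc_date` — Bayesian node dating by Metropolis-Hastings over
  node ages, substitution rate and kappa, with uniform calibration
  priors (a uniform root-age calibration, plus an optional internal-node
  calibration such as the human-Neanderthal split);
* :func:`run_table2_models` — the four standard calibration models
  (root 6-8 or 5-6 Myr, internal 0.5-0.8 Myr or absent).

Node ages are in years; rates in substitutions per site per year.
Internally ages are parameterized as a root age plus per-node
proportions in (0,1), so node-age priors are uniform in that
parameterization and parent > child holds by construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .synthetic_data import SimNode

__all__ = [
    "ClockModelConfig",
    "ClockTestResult",
    "PosteriorSummary",
    "Topology",
    "hky_transition_matrix",
    "hky_transition_matrices",
    "hky_loglik",
    "make_loglik_fn",
    "empirical_freqs",
    "clock_lrt",
    "mcmc_date",
    "run_table2_models",
    "TABLE2_MODELS",
]


# ---------------------------------------------------------------------------
# topology container


class Topology:
    """Rooted binary topology stored as postorder arrays for fast pruning."""

    def __init__(self, children: list[tuple[int, int] | None], labels: list[str | None]):
        self.children = children  # per node: (left, right) or None for tips
        self.labels = labels
        self.n_nodes = len(children)
        self.tips = [i for i, c in enumerate(children) if c is None]
        self.internal = [i for i, c in enumerate(children) if c is not None]
        self.root = self.n_nodes - 1
        self.parent = [-1] * self.n_nodes
        for i, c in enumerate(children):
            if c is not None:
                for child in c:
                    self.parent[child] = i
        self.postorder = self._postorder()

    def _postorder(self) -> list[int]:
        order, stack = [], [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done or self.children[node] is None:
                order.append(node)
            else:
                stack.append((node, True))
                for ch in self.children[node]:
                    stack.append((ch, False))
        return order

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tips]

    def clade_leafsets(self) -> dict[int, frozenset]:
        out: dict[int, frozenset] = {}
        for node in self.postorder:
            if self.children[node] is None:
                out[node] = frozenset([self.labels[node]])
            else:
                l, r = self.children[node]
                out[node] = out[l] | out[r]
        return out

    @classmethod
    def from_newick(cls, newick: str) -> "Topology":
        import dendropy

        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls.from_dendropy(tree)

    @classmethod
    def from_dendropy(cls, tree) -> "Topology":
        children: list[tuple[int, int] | None] = []
        labels: list[str | None] = []
        index: dict = {}

        def visit(node) -> int:
            kids = node.child_nodes()
            if not kids:
                children.append(None)
                labels.append(node.taxon.label)
            else:
                if len(kids) != 2:
                    # resolve multifurcations arbitrarily but deterministically
                    ids = [visit(k) for k in kids]
                    while len(ids) > 2:
                        a, b = ids.pop(0), ids.pop(0)
                        children.append((a, b))
                        labels.append(None)
                        ids.insert(0, len(children) - 1)
                    children.append(tuple(ids))
                    labels.append(node.label)
                    index[node] = len(children) - 1
                    return len(children) - 1
                ids = tuple(visit(k) for k in kids)
                children.append(ids)
                labels.append(node.label)
            index[node] = len(children) - 1
            return len(children) - 1

        visit(tree.seed_node)
        return cls(children, labels)

    @classmethod
    def from_simnode(cls, root: SimNode) -> "Topology":
        children: list[tuple[int, int] | None] = []
        labels: list[str | None] = []

        def visit(node: SimNode) -> int:
            if node.is_leaf:
                children.append(None)
                labels.append(node.name)
            else:
                kids = [visit(c) for c in node.children]
                while len(kids) > 2:
                    a, b = kids.pop(0), kids.pop(0)
                    children.append((a, b))
                    labels.append(None)
                    kids.insert(0, len(children) - 1)
                children.append(tuple(kids))
                labels.append(node.name)
            return len(children) - 1

        visit(root)
        return cls(children, labels)


# ---------------------------------------------------------------------------
# HKY85 likelihood


def hky_transition_matrix(t: float, kappa: float, freqs: np.ndarray) -> np.ndarray:
    """Analytic HKY85 transition probability matrix P(t).

    ``t`` is expected substitutions per site (branch length); the rate
    matrix is scaled so its mean substitution rate is 1.  Base order is
    A, C, G, T.
    """
    fa, fc, fg, ft = freqs
    pr, py = fa + fg, fc + ft
    mu = 1.0 / (2 * kappa * (fa * fg + fc * ft) + 2 * pr * py)
    e2 = math.exp(-mu * t)
    P = np.empty((4, 4))
    group = {0: (pr, (0, 2)), 1: (py, (1, 3)), 2: (pr, (0, 2)), 3: (py, (1, 3))}
    e3 = {}
    for g, pg in (("R", pr), ("Y", py)):
        e3[g] = math.exp(-mu * t * (pg * kappa + 1 - pg))
    for i in range(4):
        pg, members = group[i]
        gname = "R" if i in (0, 2) else "Y"
        for j in range(4):
            fj = freqs[j]
            if j == i:
                P[i, j] = fj + fj * (1 / pg - 1) * e2 + ((pg - fj) / pg) * e3[gname]
            elif j in members:  # transition
                P[i, j] = fj + fj * (1 / pg - 1) * e2 - (fj / pg) * e3[gname]
            else:  # transversion
                P[i, j] = fj * (1 - e2)
    return P


def hky_transition_matrices(
    ts: np.ndarray, kappa: float, freqs: np.ndarray
) -> np.ndarray:
    """Vectorized :func:`hky_transition_matrix` for an array of lengths."""
    # P(t) = A + B e2(t) + C_R e3R(t) + C_Y e3Y(t), with coefficient
    # matrices depending on the frequencies only
    ts = np.asarray(ts, dtype=float)
    fa, fc, fg, ft = freqs
    pr, py = fa + fg, fc + ft
    A, B, CR, CY = _hky_coeffs(float(fa), float(fc), float(fg), float(ft))
    mu = 1.0 / (2 * kappa * (fa * fg + fc * ft) + 2 * pr * py)
    e2 = np.exp(-mu * ts)[:, None, None]
    e3r = np.exp(-mu * ts * (pr * kappa + 1 - pr))[:, None, None]
    e3y = np.exp(-mu * ts * (py * kappa + 1 - py))[:, None, None]
    return A + B * e2 + CR * e3r + CY * e3y


from functools import lru_cache


@lru_cache(maxsize=8)
def _hky_coeffs(fa: float, fc: float, fg: float, ft: float):
    freqs = (fa, fc, fg, ft)
    pr, py = fa + fg, fc + ft
    A = np.empty((4, 4))
    B = np.empty((4, 4))
    CR = np.zeros((4, 4))
    CY = np.zeros((4, 4))
    for i in range(4):
        purine = i in (0, 2)
        pg = pr if purine else py
        C = CR if purine else CY
        members = (0, 2) if purine else (1, 3)
        for j in range(4):
            fj = freqs[j]
            A[i, j] = fj
            if j == i:
                B[i, j] = fj * (1 / pg - 1)
                C[i, j] = (pg - fj) / pg
            elif j in members:
                B[i, j] = fj * (1 / pg - 1)
                C[i, j] = -fj / pg
            else:
                B[i, j] = -fj
    return A, B, CR, CY


def _pattern_compress(rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique site patterns and their counts; rows are (n_tips, L) codes."""
    patterns, counts = np.unique(rows.T, axis=0, return_counts=True)
    return patterns.T, counts.astype(float)


_TIP_LIK = np.vstack([np.eye(4), np.ones(4)])  # code 4 = missing


def make_loglik_fn(patterns: np.ndarray, counts: np.ndarray, topo: Topology,
                   freqs: np.ndarray):
    """Compiled pruning closure f(branch_lengths, kappa) -> log-likelihood.

    Tip partials and the traversal order are precomputed; each call only
    builds the per-edge transition matrices and runs the matmul chain.
    Used by the optimizer and the MCMC sampler.
    """
    freqs = np.asarray(freqs, dtype=float)
    tip_partials = {
        node: _TIP_LIK[patterns[k]] for k, node in enumerate(topo.tips)
    }
    internal_ops = [
        (node, *topo.children[node])
        for node in topo.postorder
        if topo.children[node] is not None
    ]
    root = topo.root
    log = np.log

    def f(branch_lengths: np.ndarray, kappa: float) -> float:
        P = hky_transition_matrices(branch_lengths, kappa, freqs)
        store: dict[int, np.ndarray] = dict(tip_partials)
        for node, l, r in internal_ops:
            store[node] = (store[l] @ P[l].T) * (store[r] @ P[r].T)
        site_lik = store[root] @ freqs
        if np.any(site_lik <= 0):
            return -np.inf
        return float(counts @ log(site_lik))

    return f


def hky_loglik(
    rows: np.ndarray,
    topo: Topology,
    branch_lengths: np.ndarray,
    kappa: float,
    freqs: np.ndarray,
    tip_order: list[str] | None = None,
    _compressed: tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    """Felsenstein-pruning log-likelihood under HKY85.

    ``rows`` holds tip sequences as integer codes (0..3 = ACGT, 4 =
    gap/N), one row per tip in ``tip_order`` (defaults to
    ``topo.tip_labels()`` order).  ``branch_lengths[i]`` is the length of
    the edge above node i (expected substitutions/site); the root entry
    is ignored.
    """
    freqs = np.asarray(freqs, dtype=float)
    if abs(freqs.sum() - 1) > 1e-8 or np.any(freqs < 0):
        raise ValueError("frequencies must be non-negative and sum to 1")
    if np.any(np.asarray(branch_lengths)[: topo.n_nodes - 1] < 0):
        raise ValueError("branch lengths must be >= 0")
    observed = np.unique(rows[rows < 4])
    if np.any(freqs[observed] == 0):
        raise ValueError("observed base has zero frequency")

    if _compressed is None:
        patterns, counts = _pattern_compress(rows)
    else:
        patterns, counts = _compressed
    if tip_order is not None:
        order = [tip_order.index(lbl) for lbl in topo.tip_labels()]
        patterns = patterns[order]

    P = hky_transition_matrices(
        np.asarray(branch_lengths, dtype=float), kappa, freqs
    )
    partial = {}
    tip_idx = {node: k for k, node in enumerate(topo.tips)}
    for node in topo.postorder:
        if topo.children[node] is None:
            partial[node] = _TIP_LIK[patterns[tip_idx[node]]]
            continue
        l, r = topo.children[node]
        partial[node] = (partial[l] @ P[l].T) * (partial[r] @ P[r].T)
        for ch in (l, r):
            partial.pop(ch)
    site_lik = partial[topo.root] @ freqs
    if np.any(site_lik <= 0):
        return -np.inf
    return float(counts @ np.log(site_lik))


def empirical_freqs(rows: np.ndarray) -> np.ndarray:
    counts = np.bincount(rows[rows < 4].ravel(), minlength=4).astype(float)
    counts = np.clip(counts, 1.0, None)
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# clock likelihood-ratio test


@dataclass(frozen=True)
class ClockTestResult:
    lr: float  # 2 * (lnL_free - lnL_clock)
    df: int  # n_tips - 2
    p_value: float
    loglik_free: float
    loglik_clock: float
    kappa_free: float
    kappa_clock: float


def _heights_from_params(topo: Topology, root_h: float, props: np.ndarray) -> np.ndarray:
    """Node heights: root height and per-internal-node proportions."""
    h = np.zeros(topo.n_nodes)
    h[topo.root] = root_h
    k = 0
    for node in reversed(topo.postorder):  # preorder
        if topo.children[node] is None or node == topo.root:
            continue
        h[node] = h[topo.parent[node]] * props[k]
        k += 1
    return h


def _clock_branch_lengths(topo: Topology, heights: np.ndarray) -> np.ndarray:
    bl = np.zeros(topo.n_nodes)
    for node in range(topo.n_nodes):
        if node != topo.root:
            bl[node] = heights[topo.parent[node]] - heights[node]
    return bl


def clock_lrt(
    rows: np.ndarray,
    topo: Topology,
    tip_order: list[str] | None = None,
    kappa_init: float = 4.0,
) -> ClockTestResult:
    """Likelihood-ratio test of the strict molecular clock.

    Free model: independent branch lengths (one root-adjacent edge fixed
    to zero, since only the sum of the two root edges is identifiable for
    a reversible model).  Clock model: ultrametric heights.  The LR
    statistic is compared with chi-square(n_tips - 2).
    """
    if topo.n_tips < 3:
        raise ValueError("need at least 3 tips")
    freqs = empirical_freqs(rows)
    compressed = _pattern_compress(rows)
    if tip_order is not None:
        order = [tip_order.index(lbl) for lbl in topo.tip_labels()]
        compressed = (compressed[0][order], compressed[1])
        tip_order = None

    llfn = make_loglik_fn(compressed[0], compressed[1], topo, freqs)

    root_l, root_r = topo.children[topo.root]
    free_edges = [i for i in range(topo.n_nodes) if i not in (topo.root, root_r)]

    def free_nll(x: np.ndarray) -> float:
        bl = np.zeros(topo.n_nodes)
        bl[free_edges] = np.exp(x[:-1])
        return -llfn(bl, math.exp(x[-1]))

    n_internal_nonroot = len(topo.internal) - 1

    def clock_nll(x: np.ndarray) -> float:
        root_h = math.exp(x[0])
        props = 1.0 / (1.0 + np.exp(-x[1 : 1 + n_internal_nonroot]))
        h = _heights_from_params(topo, root_h, props)
        bl = _clock_branch_lengths(topo, h)
        return -llfn(bl, math.exp(x[-1]))

    x0 = np.concatenate([np.full(len(free_edges), math.log(0.02)),
                         [math.log(kappa_init)]])
    res_free = optimize.minimize(free_nll, x0, method="L-BFGS-B")
    x0c = np.concatenate([[math.log(0.02)], np.zeros(n_internal_nonroot),
                          [math.log(kappa_init)]])
    res_clock = optimize.minimize(clock_nll, x0c, method="L-BFGS-B")
    if not (res_free.success and res_clock.success):
        raise RuntimeError(
            f"optimizer did not converge: free={res_free.message} "
            f"clock={res_clock.message}"
        )
    lr = 2.0 * (res_clock.fun - res_free.fun)
    if lr < 0:
        # nested models: retry the free fit from the clock solution
        x1 = np.concatenate([np.full(len(free_edges), math.log(1e-4)),
                             [res_clock.x[-1]]])
        res_free2 = optimize.minimize(free_nll, x1, method="L-BFGS-B")
        if res_free2.fun < res_free.fun:
            res_free = res_free2
        lr = max(0.0, 2.0 * (res_clock.fun - res_free.fun))
    df = topo.n_tips - 2
    p = float(stats.chi2.sf(lr, df))
    return ClockTestResult(
        lr=float(lr),
        df=df,
        p_value=p,
        loglik_free=-float(res_free.fun),
        loglik_clock=-float(res_clock.fun),
        kappa_free=float(math.exp(res_free.x[-1])),
        kappa_clock=float(math.exp(res_clock.x[-1])),
    )


# ---------------------------------------------------------------------------
# Bayesian MCMC dating


@dataclass
class ClockModelConfig:
    """Calibration priors for one dating model.

    ``root_bounds``: uniform prior on the root age in years (required).
    ``internal_bounds``: optional uniform calibration on the age of the
    clade whose tip labels are ``internal_clade`` (e.g. the
    human+Neanderthal split).  Rate and kappa get log-uniform priors.
    """

    root_bounds: tuple[float, float]
    internal_bounds: tuple[float, float] | None = None
    internal_clade: frozenset | None = None
    rate_bounds: tuple[float, float] = (1e-11, 1e-6)
    kappa_bounds: tuple[float, float] = (0.5, 200.0)

    def __post_init__(self) -> None:
        lo, hi = self.root_bounds
        if not 0 < lo < hi:
            raise ValueError("root bounds must be positive with min < max")
        if (self.internal_bounds is None) != (self.internal_clade is None):
            raise ValueError("internal calibration needs both bounds and clade")
        if self.internal_bounds is not None:
            lo, hi = self.internal_bounds
            if not 0 < lo < hi:
                raise ValueError("internal bounds must be positive with min < max")


@dataclass
class ChainSettings:
    n_iter: int = 4000  # sweeps (each sweep updates every parameter once)
    burn_in: int = 1000
    thin: int = 2
    root_step: float = 0.3  # fraction of the root calibration width
    prop_step: float = 0.15
    log_step: float = 0.4


@dataclass
class PosteriorSummary:
    """Posterior node ages (years) for one model run."""

    node_ages_mean: dict[str, float]
    node_ages_ci: dict[str, tuple[float, float]]
    rate_mean: float
    kappa_mean: float
    ess: dict[str, float]
    seed: int
    n_samples: int
    acceptance: dict[str, float] = field(default_factory=dict)
    low_ess: bool = False

    def age(self, clade_name: str) -> float:
        return self.node_ages_mean[clade_name]


def _ess(x: np.ndarray) -> float:
    """Effective sample size by the initial positive sequence estimator."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 10 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1 :] / (np.arange(n, 0, -1) * np.var(x))
    s = 0.0
    for k in range(1, n // 2):
        pair = acf[2 * k - 1] + acf[2 * k] if 2 * k < n else 0.0
        if pair <= 0:
            break
        s += pair
    return float(n / (1 + 2 * s))


def mcmc_date(
    rows: np.ndarray,
    topo: Topology,
    config: ClockModelConfig,
    settings: ChainSettings | None = None,
    seed: int = 0,
    tip_order: list[str] | None = None,
    prior_only: bool = False,
    clock_warning: ClockTestResult | None = None,
) -> PosteriorSummary:
    """Metropolis-Hastings sampler for node ages under a strict clock.

    State: root age (uniform calibration prior), per-node age proportions
    in (0,1) (uniform priors, so parent > child always holds),
    substitution rate and kappa (log-uniform).  An optional internal
    calibration truncates the corresponding node age.  Deterministic for
    a given seed.  ``prior_only=True`` drops the likelihood term, so the
    chain samples the calibration priors.
    """
    settings = settings or ChainSettings()
    if clock_warning is not None and clock_warning.p_value < 0.05:
        warnings.warn("strict clock rejected by the LRT; dates may be biased")
    rng = np.random.default_rng(seed)
    freqs = empirical_freqs(rows)
    compressed = _pattern_compress(rows)
    if tip_order is not None:
        order = [tip_order.index(lbl) for lbl in topo.tip_labels()]
        compressed = (compressed[0][order], compressed[1])

    llfn = make_loglik_fn(compressed[0], compressed[1], topo, freqs)

    leafsets = topo.clade_leafsets()
    internal_nonroot = [n for n in topo.internal if n != topo.root]
    cal_node = None
    if config.internal_clade is not None:
        for node, ls in leafsets.items():
            if ls == config.internal_clade:
                cal_node = node
        if cal_node is None:
            raise ValueError("internal calibration clade not found in topology")

    rlo, rhi = config.root_bounds

    def ages_from(root_age: float, props: np.ndarray) -> np.ndarray:
        h = np.zeros(topo.n_nodes)
        h[topo.root] = root_age
        for k, node in enumerate(internal_nonroot_preorder):
            h[node] = h[topo.parent[node]] * props[order_index[node]]
        return h

    internal_nonroot_preorder = [
        n for n in reversed(topo.postorder) if n in set(internal_nonroot)
    ]
    order_index = {n: k for k, n in enumerate(internal_nonroot_preorder)}

    def log_post(root_age: float, props: np.ndarray, log_rate: float,
                 log_kappa: float) -> float:
        if not rlo <= root_age <= rhi:
            return -np.inf
        if np.any(props <= 0) or np.any(props >= 1):
            return -np.inf
        if not math.log(config.rate_bounds[0]) <= log_rate <= math.log(config.rate_bounds[1]):
            return -np.inf
        if not math.log(config.kappa_bounds[0]) <= log_kappa <= math.log(config.kappa_bounds[1]):
            return -np.inf
        ages = ages_from(root_age, props)
        if cal_node is not None:
            lo, hi = config.internal_bounds
            if not lo <= ages[cal_node] <= hi:
                return -np.inf
        if prior_only:
            return 0.0
        rate = math.exp(log_rate)
        bl = _clock_branch_lengths(topo, ages) * rate
        return llfn(bl, math.exp(log_kappa))

    # initial state
    root_age = 0.5 * (rlo + rhi)
    props = np.full(len(internal_nonroot), 0.5)
    if cal_node is not None:
        # start the calibrated node inside its bounds
        lo, hi = config.internal_bounds
        target = 0.5 * (lo + hi)
        path = []
        node = cal_node
        while node != topo.root:
            path.append(node)
            node = topo.parent[node]
        frac = (target / root_age) ** (1 / len(path))
        for nd in path:
            props[order_index[nd]] = frac
    log_rate = math.log(math.sqrt(config.rate_bounds[0] * config.rate_bounds[1]))
    if not prior_only:
        log_rate = math.log(2e-8)
    log_kappa = math.log(10.0)

    lp = log_post(root_age, props, log_rate, log_kappa)
    if not np.isfinite(lp):
        raise RuntimeError("invalid initial MCMC state")

    n_keep = (settings.n_iter - settings.burn_in) // settings.thin
    age_trace = np.empty((n_keep, topo.n_nodes))
    rate_trace = np.empty(n_keep)
    kappa_trace = np.empty(n_keep)
    accepts = {"root": 0, "props": 0, "rate": 0, "kappa": 0}
    tries = {k: 0 for k in accepts}
    kept = 0

    def reflect(x: float, lo: float, hi: float) -> float:
        width = hi - lo
        while x < lo or x > hi:
            if x < lo:
                x = 2 * lo - x
            if x > hi:
                x = 2 * hi - x
        return x

    for it in range(settings.n_iter):
        # root age
        tries["root"] += 1
        prop_root = reflect(
            root_age + (rng.random() - 0.5) * 2 * settings.root_step * (rhi - rlo),
            rlo, rhi,
        )
        lp_new = log_post(prop_root, props, log_rate, log_kappa)
        if math.log(rng.random() + 1e-300) < lp_new - lp:
            root_age, lp = prop_root, lp_new
            accepts["root"] += 1
        # proportions, one at a time
        for k in range(props.size):
            tries["props"] += 1
            new_props = props.copy()
            new_props[k] = reflect(
                props[k] + (rng.random() - 0.5) * 2 * settings.prop_step, 0.0, 1.0
            )
            lp_new = log_post(root_age, new_props, log_rate, log_kappa)
            if math.log(rng.random() + 1e-300) < lp_new - lp:
                props, lp = new_props, lp_new
                accepts["props"] += 1
        if not prior_only:
            for name in ("rate", "kappa"):
                tries[name] += 1
                delta = (rng.random() - 0.5) * 2 * settings.log_step
                if name == "rate":
                    cand = log_rate + delta
                    lp_new = log_post(root_age, props, cand, log_kappa)
                else:
                    cand = log_kappa + delta
                    lp_new = log_post(root_age, props, log_rate, cand)
                if math.log(rng.random() + 1e-300) < lp_new - lp:
                    lp = lp_new
                    if name == "rate":
                        log_rate = cand
                    else:
                        log_kappa = cand
                    accepts[name] += 1
        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            if kept < n_keep:
                age_trace[kept] = ages_from(root_age, props)
                rate_trace[kept] = math.exp(log_rate)
                kappa_trace[kept] = math.exp(log_kappa)
                kept += 1

    age_trace = age_trace[:kept]
    names = _node_names(topo, leafsets)
    means, cis, ess = {}, {}, {}
    for node in topo.internal:
        trace = age_trace[:, node]
        means[names[node]] = float(trace.mean())
        cis[names[node]] = (
            float(np.quantile(trace, 0.025)),
            float(np.quantile(trace, 0.975)),
        )
        ess[names[node]] = _ess(trace)
    ess["rate"] = _ess(rate_trace[:kept])
    low = any(v < 100 for v in ess.values())
    if low:
        warnings.warn("low effective sample size; consider a longer chain")
    return PosteriorSummary(
        node_ages_mean=means,
        node_ages_ci=cis,
        rate_mean=float(rate_trace[:kept].mean()),
        kappa_mean=float(kappa_trace[:kept].mean()),
        ess=ess,
        seed=seed,
        n_samples=kept,
        acceptance={k: accepts[k] / max(tries[k], 1) for k in accepts},
        low_ess=low,
    )


def _node_names(topo: Topology, leafsets: dict[int, frozenset]) -> dict[int, str]:
    """Stable internal-node names: smallest two leaf labels of the clade."""
    names = {}
    for node in topo.internal:
        lbl = topo.labels[node]
        if lbl:
            names[node] = lbl
        else:
            ls = sorted(leafsets[node])
            names[node] = f"mrca({ls[0]},{ls[-1]})" if node != topo.root else "root"
    names[topo.root] = "root"
    return names


#: Table-2-style calibration presets: (root bounds, internal bounds or None).
TABLE2_MODELS: dict[int, tuple[tuple[float, float], tuple[float, float] | None]] = {
    1: ((6.0e6, 8.0e6), None),
    2: ((6.0e6, 8.0e6), (5.0e5, 8.0e5)),
    3: ((5.0e6, 6.0e6), None),
    4: ((5.0e6, 6.0e6), (5.0e5, 8.0e5)),
}


def run_table2_models(
    rows: np.ndarray,
    topo: Topology,
    human_nea_clade: frozenset,
    settings: ChainSettings | None = None,
    seed: int = 0,
    tip_order: list[str] | None = None,
) -> dict[int, PosteriorSummary]:
    """Run the four calibration models on one panel.

    Models 1/2 put the root (human-chimp) calibration at 6-8 Myr, models
    3/4 at 5-6 Myr; models 2/4 additionally calibrate the
    human-Neanderthal split at 0.5-0.8 Myr.
    """
    out = {}
    for model, (root_bounds, internal) in TABLE2_MODELS.items():
        config = ClockModelConfig(
            root_bounds=root_bounds,
            internal_bounds=internal,
            internal_clade=human_nea_clade if internal else None,
        )
        out[model] = mcmc_date(
            rows, topo, config, settings=settings, seed=seed + model,
            tip_order=tip_order,
        )
    return out
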
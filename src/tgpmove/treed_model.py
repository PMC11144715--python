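"""Bayesian treed partition over standardized time with a GP at each leaf.

A binary tree recursively splits the time domain [0, 1]; each leaf interval
gets an independent stationary GP (see :mod:`tgpmove.gp_core`).  The tree
prior is the Bayesian-CART process: a node at depth ``q`` splits with
probability ``alpha * (1 + q)^(-beta)`` (whenever a valid split exists), and
the split value is uniform over the candidate set within the node's interval
that leaves both children with at least ``min_leaf_size`` observations.
Candidate splits are the midpoints between consecutive distinct observed
times, making the uniform split mass proper.

Posterior exploration is reversible-jump Metropolis-Hastings over tree
structures (grow / prune / change / swap moves) interleaved with random-walk
updates of each leaf's correlation hyperparameters.  Newly created leaves
receive hyperparameters drawn from the hyperprior, the simplest valid
dimension-matching scheme, so the hyperprior densities cancel from the
grow/prune acceptance ratio.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .gp_core import (
    GPHyperParams,
    GPPriorConfig,
    LeafData,
    NumericalError,
    log_marginal_likelihood,
    update_hyperparameters,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# tree structure
# ---------------------------------------------------------------------------

@dataclass
class _Node:
    split: float | None = None
    left: "_Node | None" = None
    right: "_Node | None" = None
    hyper: GPHyperParams | None = None  # set on leaves only

    @property
    def is_leaf(self) -> bool:
        return self.split is None


@dataclass(frozen=True)
class _NodeRec:
    """One node during traversal: its path from the root (0=left, 1=right),
    covered interval [lo, hi) and depth."""
    node: _Node
    path: tuple[int, ...]
    lo: float
    hi: float
    depth: int


class PartitionTree:
    """Binary partition of [0, 1] with per-leaf GP hyperparameters.

    Leaf intervals are left-closed/right-open, except the rightmost leaf
    which is closed at 1.  Leaf ids are in-order (left to right) indices.
    """

    def __init__(self, root: _Node | None = None,
                 hyper: GPHyperParams | None = None):
        if root is None:
            root = _Node(hyper=hyper or GPHyperParams(d=0.1, g=0.01))
        self.root = root

    # -- traversal ---------------------------------------------------------
    def _walk(self):
        stack = [_NodeRec(self.root, (), 0.0, 1.0, 0)]
        while stack:
            rec = stack.pop()
            yield rec
            node = rec.node
            if not node.is_leaf:
                stack.append(_NodeRec(node.right, rec.path + (1,),
                                      node.split, rec.hi, rec.depth + 1))
                stack.append(_NodeRec(node.left, rec.path + (0,),
                                      rec.lo, node.split, rec.depth + 1))

    def leaves(self) -> list[_NodeRec]:
        out = [r for r in self._walk() if r.node.is_leaf]
        return sorted(out, key=lambda r: r.lo)

    def internal(self) -> list[_NodeRec]:
        return [r for r in self._walk() if not r.node.is_leaf]

    def node_at(self, path: tuple[int, ...]) -> _Node:
        node = self.root
        for step in path:
            node = node.right if step else node.left
        return node

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    @property
    def depth(self) -> int:
        return max(r.depth for r in self._walk())

    def split_times(self) -> tuple[float, ...]:
        return tuple(sorted(r.node.split for r in self.internal()))

    def clone(self) -> "PartitionTree":
        return PartitionTree(copy.deepcopy(self.root))

    @property
    def leaf_params(self) -> list[GPHyperParams]:
        return [r.node.hyper for r in self.leaves()]


@dataclass(frozen=True)
class TGPState:
    """One MCMC state: the partition tree (leaf hyperparameters live on the
    leaf nodes)."""
    tree: PartitionTree

    @property
    def leaf_params(self) -> list[GPHyperParams]:
        return self.tree.leaf_params


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MoveProbs:
    grow: float = 0.2
    prune: float = 0.2
    change: float = 0.4
    swap: float = 0.2

    def __post_init__(self) -> None:
        probs = (self.grow, self.prune, self.change, self.swap)
        if any(p < 0 for p in probs) or sum(probs) > 1 + 1e-12:
            raise ValueError("move probabilities must be non-negative and sum to <= 1")


@dataclass(frozen=True)
class ChainConfig:
    """MCMC run configuration.

    Defaults follow the study settings: 12,000 total iterations, burn-in of
    2,000 and thinning by 10, retaining K = 1,000 states.
    """

    n_iter: int = 12000
    burn_in: int = 2000
    thin: int = 10
    tree_alpha: float = 0.5
    tree_beta: float = 2.0
    min_leaf_size: int = 10
    moves: MoveProbs = field(default_factory=MoveProbs)
    power: float = 2.0
    step_d: float = 0.5
    step_g: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if (self.n_iter - self.burn_in) % self.thin != 0:
            raise ValueError("(n_iter - burn_in) must be a multiple of thin")
        if not (0 < self.tree_alpha < 1):
            raise ValueError("tree_alpha must lie in (0, 1)")
        if self.tree_beta < 0:
            raise ValueError("tree_beta must be >= 0")
        if self.min_leaf_size < 1:
            raise ValueError("min_leaf_size must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


def force_stationary(config: ChainConfig) -> ChainConfig:
    """Return a configuration whose chain never grows the tree, so the model
    reduces to a single stationary GP baseline."""
    return replace(config, moves=MoveProbs(grow=0.0, prune=0.0,
                                           change=0.0, swap=0.0))


@dataclass(frozen=True)
class PosteriorChain:
    """Retained MCMC states plus the per-iteration log joint density trace."""
    states: list[TGPState]
    log_joint: np.ndarray
    config: ChainConfig

    @property
    def n_retained(self) -> int:
        return len(self.states)


# ---------------------------------------------------------------------------
# prior
# ---------------------------------------------------------------------------

def split_probability(depth: int, a: float, b: float) -> float:
    """Bayesian-CART split probability ``a (1 + depth)^(-b)``."""
    if depth < 0:
        raise ValueError("depth must be non-negative")
    if not (0 < a < 1) or b < 0:
        raise ValueError("need 0 < a < 1 and b >= 0")
    return a * (1.0 + depth) ** (-b)


def candidate_splits(times: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct observed times."""
    t = np.unique(np.asarray(times, dtype=float))
    return (t[:-1] + t[1:]) / 2.0


def _slice_bounds(times: np.ndarray, lo: float, hi: float) -> tuple[int, int]:
    i0 = int(np.searchsorted(times, lo, side="left"))
    i1 = times.size if hi >= 1.0 else int(np.searchsorted(times, hi, side="left"))
    return i0, i1


def _valid_splits(times: np.ndarray, cands: np.ndarray, lo: float, hi: float,
                  min_leaf: int) -> np.ndarray:
    """Candidates within (lo, hi) leaving >= min_leaf points on each side."""
    i0, i1 = _slice_bounds(times, lo, hi)
    sel = cands[(cands > lo) & (cands < hi)]
    if sel.size == 0:
        return sel
    left_counts = np.searchsorted(times[i0:i1], sel, side="left")
    right_counts = (i1 - i0) - left_counts
    return sel[(left_counts >= min_leaf) & (right_counts >= min_leaf)]


def tree_log_prior(tree: PartitionTree, times: np.ndarray, cands: np.ndarray,
                   a: float, b: float, min_leaf_size: int) -> float:
    """Log prior of a tree: split/stop probabilities at every node plus the
    uniform candidate-split mass at each internal node.

    A node with no valid candidate split has split probability zero, so the
    prior sums to one over the (finite) set of valid trees; an invalid tree
    gets -inf.
    """
    total = 0.0
    for rec in tree._walk():
        valid = _valid_splits(times, cands, rec.lo, rec.hi, min_leaf_size)
        p = split_probability(rec.depth, a, b) if valid.size else 0.0
        if rec.node.is_leaf:
            total += math.log1p(-p) if p > 0 else 0.0
        else:
            if p == 0.0 or rec.node.split not in valid:
                return -np.inf
            total += math.log(p) - math.log(valid.size)
    return total


def sample_tree_from_prior(times: np.ndarray, cands: np.ndarray, a: float,
                           b: float, min_leaf_size: int,
                           rng: np.random.Generator,
                           prior: GPPriorConfig | None = None,
                           power: float = 2.0) -> PartitionTree:
    """Direct simulation from the tree prior (used as a recovery oracle)."""
    prior = prior or GPPriorConfig()

    def build(lo: float, hi: float, depth: int) -> _Node:
        valid = _valid_splits(times, cands, lo, hi, min_leaf_size)
        p = split_probability(depth, a, b) if valid.size else 0.0
        if valid.size and rng.random() < p:
            c = float(rng.choice(valid))
            return _Node(split=c, left=build(lo, c, depth + 1),
                         right=build(c, hi, depth + 1))
        return _Node(hyper=prior.draw_hyperparams(rng, p=power))

    return PartitionTree(build(0.0, 1.0, 0))


def assign_leaves(tree: PartitionTree, times: np.ndarray) -> np.ndarray:
    """Map each time in [0, 1] to its leaf id (in-order index).

    Intervals are left-closed/right-open; the final interval is closed at 1.
    """
    t = np.asarray(times, dtype=float)
    if t.size and (t.min() < 0 or t.max() > 1):
        raise ValueError("times must lie in [0, 1]")
    leaves = tree.leaves()
    edges = np.array([r.lo for r in leaves[1:]])
    return np.searchsorted(edges, t, side="right")


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------

class _LeafLikCache:
    """Memoizes per-leaf marginal likelihoods keyed by (interval, d, g, p)."""

    def __init__(self, times: np.ndarray, values: np.ndarray,
                 prior: GPPriorConfig, loglik=None):
        self.times = times
        self.values = values
        self.prior = prior
        self.loglik = loglik
        self._store: dict = {}

    def leaf_data(self, lo: float, hi: float) -> LeafData:
        i0, i1 = _slice_bounds(self.times, lo, hi)
        return LeafData(times=self.times[i0:i1], values=self.values[i0:i1])

    def __call__(self, lo: float, hi: float, hyper: GPHyperParams) -> float:
        key = (lo, hi, hyper.d, hyper.g, hyper.p)
        if key not in self._store:
            if len(self._store) > 200_000:
                self._store.clear()
            leaf = self.leaf_data(lo, hi)
            if self.loglik is not None:
                val = self.loglik(leaf, hyper)
            else:
                val = log_marginal_likelihood(leaf, hyper, self.prior)
            self._store[key] = val
        return self._store[key]


def _tree_loglik(tree: PartitionTree, cache: _LeafLikCache) -> float:
    return sum(cache(r.lo, r.hi, r.node.hyper) for r in tree.leaves())


def _log_joint(tree: PartitionTree, cache: _LeafLikCache, cands: np.ndarray,
               config: ChainConfig, prior: GPPriorConfig) -> float:
    return (_tree_loglik(tree, cache)
            + tree_log_prior(tree, cache.times, cands, config.tree_alpha,
                             config.tree_beta, config.min_leaf_size)
            + sum(prior.log_hyperprior(h) for h in tree.leaf_params))


def _growable(tree: PartitionTree, cache: _LeafLikCache, cands, min_leaf):
    return [r for r in tree.leaves()
            if _valid_splits(cache.times, cands, r.lo, r.hi, min_leaf).size > 0]


def _prunable(tree: PartitionTree):
    return [r for r in tree.internal()
            if r.node.left.is_leaf and r.node.right.is_leaf]


def _propose_tree_move(tree: PartitionTree, cache: _LeafLikCache,
                       cands: np.ndarray, config: ChainConfig,
                       prior: GPPriorConfig, rng: np.random.Generator
                       ) -> PartitionTree:
    """One grow/prune/change/swap Metropolis-Hastings tree move; returns the
    (possibly unchanged) tree."""
    a, b, m = config.tree_alpha, config.tree_beta, config.min_leaf_size
    mv = config.moves
    u = rng.random()
    edges = np.cumsum([mv.grow, mv.prune, mv.change, mv.swap])
    if u >= edges[-1]:
        return tree
    move = ("grow", "prune", "change", "swap")[int(np.searchsorted(edges, u, side="right"))]

    def logprior(t: PartitionTree) -> float:
        return tree_log_prior(t, cache.times, cands, a, b, m)

    lp_old = logprior(tree)
    try:
        ll_old = _tree_loglik(tree, cache)
    except NumericalError:
        logger.warning("numerical error on current tree likelihood; move skipped")
        return tree

    new = None
    log_fwd = log_rev = 0.0

    if move == "grow":
        growable = _growable(tree, cache, cands, m)
        if not growable:
            return tree
        rec = growable[int(rng.integers(len(growable)))]
        valid = _valid_splits(cache.times, cands, rec.lo, rec.hi, m)
        c = float(valid[int(rng.integers(valid.size))])
        new = tree.clone()
        node = new.node_at(rec.path)
        node.split = c
        node.hyper = None
        node.left = _Node(hyper=prior.draw_hyperparams(rng, p=config.power))
        node.right = _Node(hyper=prior.draw_hyperparams(rng, p=config.power))
        log_fwd = math.log(mv.grow) - math.log(len(growable)) - math.log(valid.size)
        n_prune_new = len(_prunable(new))
        if mv.prune == 0 or n_prune_new == 0:
            return tree
        log_rev = math.log(mv.prune) - math.log(n_prune_new)

    elif move == "prune":
        prunable = _prunable(tree)
        if not prunable:
            return tree
        rec = prunable[int(rng.integers(len(prunable)))]
        new = tree.clone()
        node = new.node_at(rec.path)
        node.split = None
        node.left = node.right = None
        node.hyper = prior.draw_hyperparams(rng, p=config.power)
        log_fwd = math.log(mv.prune) - math.log(len(prunable))
        growable_new = _growable(new, cache, cands, m)
        valid_here = _valid_splits(cache.times, cands, rec.lo, rec.hi, m)
        if mv.grow == 0 or not growable_new or valid_here.size == 0:
            return tree
        log_rev = (math.log(mv.grow) - math.log(len(growable_new))
                   - math.log(valid_here.size))

    elif move == "change":
        internal = tree.internal()
        if not internal:
            return tree
        rec = internal[int(rng.integers(len(internal)))]
        valid = _valid_splits(cache.times, cands, rec.lo, rec.hi, m)
        if valid.size == 0:
            return tree
        c = float(valid[int(rng.integers(valid.size))])
        new = tree.clone()
        new.node_at(rec.path).split = c
        # node interval (hence its candidate set) is unchanged: symmetric

    else:  # swap split values between an internal node and an internal child
        pairs = [(r, side) for r in tree.internal()
                 for side in (0, 1)
                 if not (r.node.left if side == 0 else r.node.right).is_leaf]
        if not pairs:
            return tree
        rec, side = pairs[int(rng.integers(len(pairs)))]
        new = tree.clone()
        parent = new.node_at(rec.path)
        child = parent.left if side == 0 else parent.right
        parent.split, child.split = child.split, parent.split
        # tree shape unchanged: pair selection is symmetric

    lp_new = logprior(new)
    if not np.isfinite(lp_new):
        return tree
    try:
        ll_new = _tree_loglik(new, cache)
    except NumericalError:
        logger.warning("numerical error on proposed tree; move rejected")
        return tree
    log_alpha = (ll_new + lp_new + log_rev) - (ll_old + lp_old + log_fwd)
    if math.log(rng.random()) < log_alpha:
        return new
    return tree


def _hyper_sweep(tree: PartitionTree, cache: _LeafLikCache, config: ChainConfig,
                 prior: GPPriorConfig, rng: np.random.Generator) -> None:
    """In-place Metropolis update of every leaf's (d, g)."""
    for rec in tree.leaves():
        lo, hi, node = rec.lo, rec.hi, rec.node
        leaf = cache.leaf_data(lo, hi)
        loglik = lambda h, lo=lo, hi=hi: cache(lo, hi, h)
        try:
            node.hyper = update_hyperparameters(
                leaf, node.hyper, prior, rng,
                step_d=config.step_d, step_g=config.step_g, loglik=loglik)
        except NumericalError:
            logger.warning("numerical error in hyperparameter update; leaf kept")


def _step(state: TGPState, cache: _LeafLikCache, cands: np.ndarray,
          config: ChainConfig, prior: GPPriorConfig,
          rng: np.random.Generator) -> tuple[TGPState, float]:
    tree = _propose_tree_move(state.tree, cache, cands, config, prior, rng)
    if tree is state.tree:
        tree = tree.clone()
    _hyper_sweep(tree, cache, config, prior, rng)
    lj = _log_joint(tree, cache, cands, config, prior)
    return TGPState(tree=tree), lj


def mcmc_step(state: TGPState, times: np.ndarray, values: np.ndarray,
              config: ChainConfig, prior: GPPriorConfig,
              rng: np.random.Generator, loglik=None) -> TGPState:
    """One MCMC sweep: a tree move followed by a hyperparameter sweep."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    cache = _LeafLikCache(times, values, prior, loglik=loglik)
    cands = candidate_splits(times)
    new_state, _ = _step(state, cache, cands, config, prior, rng)
    return new_state


def initial_state(config: ChainConfig, prior: GPPriorConfig) -> TGPState:
    """Single-leaf tree at the hyperprior medians."""
    hyper = GPHyperParams(d=math.exp(prior.d_log_mu),
                          g=math.exp(prior.g_log_mu), p=config.power)
    return TGPState(tree=PartitionTree(hyper=hyper))


def run_chain(times: np.ndarray, values: np.ndarray, config: ChainConfig,
              prior: GPPriorConfig | None = None,
              rng: np.random.Generator | None = None,
              loglik=None) -> PosteriorChain:
    """Run the treed-GP MCMC for one coordinate and return the retained states.

    Retains every ``thin``-th state after ``burn_in``, for
    ``K = (n_iter - burn_in) / thin`` states (1,000 under the defaults).
    With fewer than ``2 * min_leaf_size`` observations no split is possible
    and the chain runs as a single-leaf stationary GP.
    """
    prior = prior or GPPriorConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    cache = _LeafLikCache(times, values, prior, loglik=loglik)
    cands = candidate_splits(times)
    state = initial_state(config, prior)
    states: list[TGPState] = []
    trace = np.empty(config.n_iter)
    for i in range(1, config.n_iter + 1):
        state, lj = _step(state, cache, cands, config, prior, rng)
        trace[i - 1] = lj
        if i > config.burn_in and (i - config.burn_in) % config.thin == 0:
            states.append(TGPState(tree=state.tree.clone()))
    assert len(states) == config.n_retained
    return PosteriorChain(states=states, log_joint=trace, config=config)
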
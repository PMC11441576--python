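"""Poisson tree processes (PTP) delimitation on a rooted tree.

The PTP model assumes two classes of branches on a gene tree: speciation
(between-species) branches and coalescent (within-species) branches, each
with i.i.d. exponential lengths at its own rate.  A delimitation is a set
of "species crown" nodes — an antichain covering every leaf — below which
all edges are coalescent-class and outside which all edges are
speciation-class, so every root-to-leaf path crosses the transition at
most once.  Rates are profiled out at their MLEs for every candidate
delimitation; a small-sample AIC guard (penalty 2 for the second rate
parameter) prevents a spurious two-class fit on rate-homogeneous trees.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np

from .io_formats import Partition

__all__ = [
    "PtpModel",
    "McmcConfig",
    "IndexedTree",
    "ptp_loglik",
    "ptp_ml_search",
    "ptp_mcmc",
]

_EPS = 1e-9  # replacement for zero-length branches


@dataclass
class PtpModel:
    lambda_speciation: float | None
    lambda_coalescent: float | None
    species_edges: frozenset[int]  # node indices whose subtending edge is speciation-class
    log_likelihood: float


@dataclass
class McmcConfig:
    n_generations: int = 500_000
    burn_in_fraction: float = 0.20
    thin: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in_fraction < 1):
            raise ValueError("burn_in_fraction must be in [0, 1)")
        if self.n_generations <= 0 or self.thin <= 0:
            raise ValueError("n_generations and thin must be positive")


class IndexedTree:
    """Array-indexed rooted tree with per-node subtree edge counts/length sums."""

    def __init__(self, tree: dendropy.Tree):
        nodes = list(tree.preorder_node_iter())
        if len(nodes) < 2:
            raise ValueError("tree has no edges")
        root = nodes[0]
        if len(root.child_nodes()) > 2:
            raise ValueError(
                "tree root has more than two children (unrooted convention); "
                "root the tree before PTP delimitation"
            )
        self.n = len(nodes)
        index = {id(nd): i for i, nd in enumerate(nodes)}
        self.parent = np.full(self.n, -1, dtype=int)
        self.blen = np.zeros(self.n)
        self.children: list[list[int]] = [[] for _ in range(self.n)]
        self.leaf_label: dict[int, str] = {}
        n_zero = 0
        for i, nd in enumerate(nodes):
            if nd is not root:
                if nd.edge.length is None:
                    raise ValueError("branch length missing on an edge; PTP requires lengths")
                if nd.edge.length < 0:
                    raise ValueError("negative branch length")
                ln = nd.edge.length
                if ln == 0:
                    ln = _EPS
                    n_zero += 1
                self.blen[i] = ln
                self.parent[i] = index[id(nd.parent_node)]
                self.children[self.parent[i]].append(i)
            if nd.is_leaf():
                label = nd.taxon.label if nd.taxon is not None else None
                if not label:
                    raise ValueError("unlabelled leaf in tree")
                self.leaf_label[i] = label
        if n_zero:
            warnings.warn(
                f"{n_zero} zero-length branch(es) perturbed to {_EPS}", stacklevel=2
            )
        # subtree aggregates (postorder = reversed preorder)
        self.sub_size = np.ones(self.n, dtype=int)  # nodes in subtree incl. self
        self.sub_len = np.zeros(self.n)  # total length of edges strictly below
        for i in range(self.n - 1, 0, -1):
            p = self.parent[i]
            self.sub_size[p] += self.sub_size[i]
            self.sub_len[p] += self.sub_len[i] + self.blen[i]
        self.n_edges = self.n - 1
        self.total_len = float(self.sub_len[0])
        self.leaves = sorted(self.leaf_label)

    def leaves_under(self, v: int) -> list[str]:
        out, stack = [], [v]
        while stack:
            u = stack.pop()
            if u in self.leaf_label:
                out.append(self.leaf_label[u])
            stack.extend(self.children[u])
        return sorted(out)

    def validate_delimitation(self, delim: frozenset[int]) -> None:
        """A valid delimitation is an antichain covering every leaf exactly once."""
        covered = 0
        for v in delim:
            u = self.parent[v]
            while u != -1:
                if u in delim:
                    raise ValueError("delimitation is not an antichain (nested crown nodes)")
                u = self.parent[u]
            covered += sum(1 for x in self._subtree(v) if x in self.leaf_label)
        if covered != len(self.leaf_label):
            raise ValueError("delimitation does not cover every leaf exactly once")

    def _subtree(self, v: int):
        stack = [v]
        while stack:
            u = stack.pop()
            yield u
            stack.extend(self.children[u])


def _class_sums(tree: IndexedTree, delim: frozenset[int]) -> tuple[int, float, int, float]:
    """(n_coal, B_coal, n_spec, B_spec): coalescent edges lie strictly below crown nodes."""
    n_coal = sum(int(tree.sub_size[v]) - 1 for v in delim)
    b_coal = float(sum(tree.sub_len[v] for v in delim))
    return n_coal, b_coal, tree.n_edges - n_coal, tree.total_len - b_coal


def _loglik_from_sums(n_c: int, b_c: float, n_s: int, b_s: float) -> tuple[float, float | None, float | None]:
    ll = 0.0
    lam_c = lam_s = None
    if n_c > 0:
        lam_c = n_c / b_c
        ll += n_c * math.log(lam_c) - n_c
    if n_s > 0:
        lam_s = n_s / b_s
        ll += n_s * math.log(lam_s) - n_s
    return ll, lam_s, lam_c


def ptp_loglik(
    tree: dendropy.Tree | IndexedTree, delimitation: frozenset[int] | set[int]
) -> tuple[float, PtpModel]:
    """Profile log-likelihood of a delimitation: rate MLE = class size / class length.

    A class with zero edges contributes nothing (single-class model).
    """
    it = tree if isinstance(tree, IndexedTree) else IndexedTree(tree)
    delim = frozenset(delimitation)
    it.validate_delimitation(delim)
    n_c, b_c, n_s, b_s = _class_sums(it, delim)
    ll, lam_s, lam_c = _loglik_from_sums(n_c, b_c, n_s, b_s)
    species_edges = frozenset(
        v for v in range(1, it.n) if not _below_crown(it, v, delim)
    )
    return ll, PtpModel(lam_s, lam_c, species_edges, ll)


def _below_crown(it: IndexedTree, v: int, delim: frozenset[int]) -> bool:
    u = it.parent[v]
    while u != -1:
        if u in delim:
            return True
        u = it.parent[u]
    return False


def _score(it: IndexedTree, delim: frozenset[int], penalize: bool = True) -> float:
    n_c, b_c, n_s, b_s = _class_sums(it, delim)
    ll, _, _ = _loglik_from_sums(n_c, b_c, n_s, b_s)
    if penalize:
        k = (n_c > 0) + (n_s > 0)
        ll -= 2.0 * (k - 1)
    return ll


def _moves(it: IndexedTree, delim: frozenset[int]) -> list[frozenset[int]]:
    """Neighbouring delimitations: split one crown node into its children, or
    merge a full sibling set into its parent."""
    out = []
    for v in delim:
        if it.children[v]:
            out.append(delim - {v} | frozenset(it.children[v]))
    parents = {it.parent[v] for v in delim if it.parent[v] != -1}
    for p in parents:
        if all(c in delim for c in it.children[p]):
            out.append(delim - frozenset(it.children[p]) | {p})
    return out


def _random_delim(it: IndexedTree, rng: np.random.Generator, p_stop: float = 0.25) -> frozenset[int]:
    """Random valid delimitation by stochastic descent from the root."""
    out: set[int] = set()
    stack = [0]
    while stack:
        v = stack.pop()
        if not it.children[v] or rng.random() < p_stop:
            out.add(v)
        else:
            stack.extend(it.children[v])
    return frozenset(out)


def delim_to_partition(it: IndexedTree, delim: frozenset[int], method: str, params: dict) -> Partition:
    assignment = {}
    for v in delim:
        leaves = it.leaves_under(v)
        name = min(leaves)
        for leaf in leaves:
            assignment[leaf] = name
    return Partition(method=method, params=params, assignment=assignment)


def ptp_ml_search(
    tree: dendropy.Tree | IndexedTree,
    n_restarts: int = 10,
    seed: int = 0,
    aic_penalty: bool = True,
) -> tuple[Partition, PtpModel]:
    """Greedy hill-climbing PTP search with seeded random restarts.

    Starts from the all-one-species delimitation (plus ``n_restarts`` random
    valid delimitations), repeatedly accepting the single best
    score-improving split/merge move.  The score is the profile
    log-likelihood minus an AIC penalty of 2 when both branch classes are
    occupied, so a rate-homogeneous tree collapses to one MOTU.
    """
    it = tree if isinstance(tree, IndexedTree) else IndexedTree(tree)
    if len(it.leaf_label) < 3:
        raise ValueError("need at least 3 leaves")
    rng = np.random.default_rng(seed)
    # deterministic extremes (one species; all singletons) plus random descents
    # with varying stopping depth — the likelihood surface between the two
    # extremes is valley-shaped, so climbing from both ends matters
    starts = [frozenset({0}), frozenset(it.leaf_label)] + [
        _random_delim(it, rng, p_stop=0.15 + 0.6 * (k % 4) / 3) for k in range(n_restarts)
    ]
    best_delim, best_score = None, -math.inf
    for start in starts:
        cur, cur_score = start, _score(it, start, aic_penalty)
        while True:
            neighbours = _moves(it, cur)
            scored = [(_score(it, nb, aic_penalty), nb) for nb in neighbours]
            top_score, top = max(scored, key=lambda x: (x[0], -len(x[1])))
            if top_score > cur_score + 1e-12:
                cur, cur_score = top, top_score
            else:
                break
        if cur_score > best_score or (
            cur_score == best_score and best_delim is not None and len(cur) < len(best_delim)
        ):
            best_delim, best_score = cur, cur_score
    ll, model = ptp_loglik(it, best_delim)
    part = delim_to_partition(
        it, best_delim, "ptp", {"n_restarts": n_restarts, "seed": seed, "logL": ll}
    )
    return part, model


def ptp_mcmc(
    tree: dendropy.Tree | IndexedTree, config: McmcConfig | None = None
) -> tuple[list[frozenset[str]], dict[str, float], Partition]:
    """Metropolis-Hastings sampler over valid delimitations (bPTP-style).

    Moves toggle one transition point (split a crown node / merge a sibling
    set); flat prior; the likelihood is the profile PTP likelihood.  The
    first ``burn_in_fraction`` of generations is discarded; the remainder is
    thinned.  Returns (sampled partitions as frozensets of MOTU leaf-label
    tuples, per-node support keyed by the smallest leaf under the node, and
    the modal sampled Partition).
    """
    it = tree if isinstance(tree, IndexedTree) else IndexedTree(tree)
    config = config or McmcConfig()
    rng = np.random.default_rng(config.seed)
    n_burn = int(config.n_generations * config.burn_in_fraction)
    if (config.n_generations - n_burn) // config.thin == 0:
        raise ValueError("no post-burn-in samples; increase n_generations or reduce thin")
    cur = frozenset({0})
    cur_ll = _score(it, cur, penalize=False)
    cur_moves = _moves(it, cur)
    samples: list[frozenset[int]] = []
    support_counts: dict[int, int] = {}
    for gen in range(config.n_generations):
        prop = cur_moves[rng.integers(len(cur_moves))]
        prop_ll = _score(it, prop, penalize=False)
        prop_moves = _moves(it, prop)
        log_alpha = (prop_ll - cur_ll) + math.log(len(cur_moves) / len(prop_moves))
        if log_alpha >= 0 or rng.random() < math.exp(log_alpha):
            cur, cur_ll, cur_moves = prop, prop_ll, prop_moves
        if gen >= n_burn and (gen - n_burn) % config.thin == 0:
            samples.append(cur)
            for v in cur:
                support_counts[v] = support_counts.get(v, 0) + 1
    n_samp = len(samples)
    support = {
        min(it.leaves_under(v)): c / n_samp for v, c in sorted(support_counts.items())
    }
    from collections import Counter

    modal_delim, _ = Counter(samples).most_common(1)[0]
    part = delim_to_partition(
        it,
        modal_delim,
        "bptp",
        {
            "n_generations": config.n_generations,
            "burn_in_fraction": config.burn_in_fraction,
            "thin": config.thin,
            "seed": config.seed,
        },
    )
    sampled_parts = [
        frozenset(tuple(it.leaves_under(v)) for v in s) for s in samples
    ]
    return sampled_parts, support, part
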
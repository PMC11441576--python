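"""Distance-based MOTU delimitation.

Three methods operating on a K2P DistanceMatrix:

* ``single_linkage_threshold`` — MOTUs are connected components of the
  graph joining pairs at distance <= cutoff (the classic fixed-threshold
  clustering behind jMOTU-style sweeps).
* ``abgd_partition`` — recursive barcode-gap partitioning: for each prior
  intraspecific divergence P, find the first significant gap in the sorted
  pairwise distances above P, split there by single linkage, and recurse
  within groups.
* ``asap_partition`` — score every single-linkage merge height as a
  candidate partition by (a) a permutation-test probability that the next
  merge would join groups drawn from one distance pool and (b) the relative
  width of the gap to the next merge; rank both, and return the partition
  with the lowest mean rank.

Saturated distances never create an edge: saturated pairs cannot be merged
by any of these methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import chi2, rankdata

from .distances import DistanceMatrix
from .io_formats import Partition

__all__ = [
    "ThresholdSweep",
    "AbgdConfig",
    "AsapScoreRow",
    "single_linkage_threshold",
    "motu_sweep",
    "abgd_partition",
    "asap_partition",
]


def _components_to_partition(
    ids: list[str], labels: np.ndarray, method: str, params: dict
) -> Partition:
    groups: dict[int, list[str]] = {}
    for sid, lab in zip(ids, labels):
        groups.setdefault(int(lab), []).append(sid)
    assignment = {}
    for members in groups.values():
        name = min(members)
        for sid in members:
            assignment[sid] = name
    return Partition(method=method, params=params, assignment=assignment)


def single_linkage_threshold(matrix: DistanceMatrix, cutoff: float) -> Partition:
    """MOTUs = connected components of the graph with edges where d <= cutoff."""
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    n = len(matrix.ids)
    adj = np.isfinite(matrix.values) & (matrix.values <= cutoff)
    np.fill_diagonal(adj, False)
    _, labels = connected_components(csr_matrix(adj), directed=False)
    return _components_to_partition(
        matrix.ids, labels, "threshold", {"cutoff": float(cutoff)}
    )


@dataclass
class ThresholdSweep:
    """Result of clustering across a ladder of cutoffs (jMOTU-style 1..50 bases)."""

    cutoffs_bases: list[int]
    cutoffs_proportion: list[float]
    motu_counts: list[int]
    partitions: list[Partition]
    excluded_short: list[str] = field(default_factory=list)

    def write_tsv(self, path, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            if self.excluded_short:
                fh.write(f"# excluded_short={','.join(self.excluded_short)}\n")
            fh.write("cutoff_bases\tcutoff_proportion\tn_motus\n")
            for b, p, c in zip(self.cutoffs_bases, self.cutoffs_proportion, self.motu_counts):
                fh.write(f"{b}\t{p:.6g}\t{c}\n")


def motu_sweep(
    matrix: DistanceMatrix,
    alignment_length: int,
    cutoffs: list[int] | None = None,
    ungapped_lengths: dict[str, int] | None = None,
    min_length_fraction: float = 0.95,
) -> ThresholdSweep:
    """Single-linkage sweep over base-unit cutoffs (default 1..50).

    Base cutoffs c are converted to proportions c/alignment_length.
    Sequences whose ungapped length is below ``min_length_fraction`` of the
    alignment length are excluded before clustering and reported.
    """
    cutoffs = list(cutoffs) if cutoffs is not None else list(range(1, 51))
    excluded: list[str] = []
    sub = matrix
    if ungapped_lengths is not None:
        min_len = min_length_fraction * alignment_length
        excluded = [s for s in matrix.ids if ungapped_lengths[s] < min_len]
        if excluded:
            sub = matrix.submatrix([s for s in matrix.ids if s not in set(excluded)])
    props, counts, parts = [], [], []
    for c in cutoffs:
        prop = c / alignment_length
        # clustering threshold: the K2P value of c transition differences,
        # so a pair differing at <= c sites always merges at cutoff c (K2P
        # corrections sit on or above the raw proportion)
        k2p_equiv = (
            -0.5 * np.log(1.0 - 2.0 * prop) if 2.0 * prop < 1.0 else np.inf
        )
        part = single_linkage_threshold(sub, float(k2p_equiv))
        part.method = "jmotu"
        part.params = {"cutoff_bases": int(c), "cutoff": prop, "k2p_cutoff": float(k2p_equiv)}
        props.append(prop)
        counts.append(part.n_motus())
        parts.append(part)
    return ThresholdSweep(cutoffs, props, counts, parts, excluded)


# ---------------------------------------------------------------------------
# Barcode-gap recursion (ABGD-style)
# ---------------------------------------------------------------------------

@dataclass
class AbgdConfig:
    """Priors and gap-detection granularity for recursive gap partitioning.

    ``prior_min``..``prior_max`` bound the assumed maximum intraspecific
    divergence P (log-spaced ladder of ``n_priors`` values); a gap between
    consecutive sorted distances is significant when wider than
    ``relative_gap_width_X`` times the local average gap over ``n_bins``
    neighbouring ranks.
    """

    prior_min: float = 0.005
    prior_max: float = 0.1
    n_priors: int = 10
    relative_gap_width_X: float = 1.0
    n_bins: int = 20

    def __post_init__(self) -> None:
        if not (0 < self.prior_min < self.prior_max < 1):
            raise ValueError("need 0 < prior_min < prior_max < 1")
        if self.relative_gap_width_X <= 0:
            raise ValueError("relative_gap_width_X must be positive")

    def priors(self) -> np.ndarray:
        return np.geomspace(self.prior_min, self.prior_max, self.n_priors)


def _first_gap(dists: np.ndarray, prior: float, X: float, n_bins: int) -> float | None:
    """Split threshold at the first significant gap located beyond the prior.

    All finite distances stay in the sorted list; a gap (d_i, d_{i+1}) is
    eligible only when its upper end exceeds the prior (distances <= prior
    are assumed intraspecific, so a gap must open beyond it — dropping the
    small distances instead would erase the barcode gap itself whenever it
    spans the prior).  The local slope at rank i is the mean of the other
    gaps within a window of ``n_bins`` ranks centred on i; an eligible gap
    wider than X times that slope is significant.  Returns the midpoint
    threshold, or None when no significant gap exists.
    """
    ds = np.sort(dists[np.isfinite(dists)])
    if ds.size < 2:
        return None
    gaps = np.diff(ds)
    if not (ds > prior).any():
        return None
    half = max(1, n_bins // 2)
    for i in range(gaps.size):
        if ds[i + 1] <= prior or gaps[i] <= 0:
            continue
        lo, hi = max(0, i - half), min(gaps.size, i + half + 1)
        others = np.concatenate([gaps[lo:i], gaps[i + 1 : hi]])
        local = others.mean() if others.size else gaps.mean()
        if local <= 0:
            local = max(float(gaps.mean()), 1e-12)
        if gaps[i] > X * local:
            return float((ds[i] + ds[i + 1]) / 2.0)
    return None


def _abgd_recurse(matrix: DistanceMatrix, prior: float, cfg: AbgdConfig) -> list[list[str]]:
    if len(matrix.ids) < 3:
        return [list(matrix.ids)]
    iu = np.triu_indices(len(matrix.ids), k=1)
    dists = matrix.values[iu]
    thr = _first_gap(dists, prior, cfg.relative_gap_width_X, cfg.n_bins)
    if thr is None:
        return [list(matrix.ids)]
    part = single_linkage_threshold(matrix, thr)
    classes = sorted(part.classes(), key=min)
    if len(classes) == 1:
        return [list(matrix.ids)]
    groups: list[list[str]] = []
    for cls_ in classes:
        groups.extend(_abgd_recurse(matrix.submatrix(cls_), prior, cfg))
    return groups


def abgd_partition(
    matrix: DistanceMatrix, config: AbgdConfig | None = None
) -> list[Partition]:
    """Recursive barcode-gap partition for each prior on the ladder.

    Degenerate priors (all distances <= prior, or no significant gap) yield
    a single MOTU.
    """
    if len(matrix.ids) < 3:
        raise ValueError("need at least 3 sequences")
    config = config or AbgdConfig()
    out = []
    for prior in config.priors():
        groups = _abgd_recurse(matrix, float(prior), config)
        assignment = {}
        for g in groups:
            name = min(g)
            for sid in g:
                assignment[sid] = name
        out.append(
            Partition(
                method="abgd",
                params={
                    "prior": float(prior),
                    "X": config.relative_gap_width_X,
                    "n_bins": config.n_bins,
                },
                assignment=assignment,
            )
        )
    return out


def abgd_stable_partition(partitions: list[Partition]) -> Partition:
    """The modal set-partition across the prior ladder (the stable plateau).

    Low priors over-split and the highest priors collapse everything, so the
    representative answer is the partition recurring for the most priors;
    ties prefer the coarser (fewer-MOTU) plateau.
    """
    from collections import Counter

    counts = Counter(p.classes() for p in partitions)
    best_classes, _ = min(
        counts.items(), key=lambda kv: (-kv[1], len(kv[0]))
    )
    for p in partitions:
        if p.classes() == best_classes:
            return p
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# Ranked-score partition selection (ASAP-style)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AsapScoreRow:
    threshold: float  # merge height defining the candidate partition
    n_motus: int
    prob: float  # Fisher-combined heterogeneity probability of the next merge
    W: float  # relative gap width to the next merge height
    prob_rank: int
    gap_rank: int
    asap_score: float


def _perm_pvalue(within: np.ndarray, between: np.ndarray, rng: np.random.Generator,
                 n_perm: int = 999) -> float:
    """One-sided rank-permutation p: are the between-group distances larger
    than the within-group distances than expected from one pooled sample?"""
    if within.size == 0 or between.size == 0:
        return 1.0
    pooled = np.concatenate([within, between])
    ranks = rankdata(pooled)
    nb = between.size
    obs = ranks[within.size :].sum()
    perm = rng.permuted(np.tile(ranks, (n_perm, 1)), axis=1)[:, :nb].sum(axis=1)
    p = float((1 + np.sum(perm >= obs)) / (1 + n_perm))
    # floor at the test's Monte-Carlo resolution: estimates below ~3/(1+n)
    # are statistically indistinguishable, and flooring keeps the candidate
    # ranking free of permutation-draw jitter among clearly significant merges
    return max(p, 3.0 / (1 + n_perm))


def asap_partition(
    matrix: DistanceMatrix,
    seed: int = 0,
    n_permutations: int = 999,
) -> tuple[list[AsapScoreRow], Partition]:
    """Score all single-linkage merge heights and return the best partition.

    Every distinct merge height h defines a candidate partition (clusters
    after all merges at height <= h).  Candidates are scored by two ranked
    metrics: (a) the probability that the first merge *above* h joins two
    groups whose cross-distances come from the same pool as their within
    distances (rank-permutation test, Fisher-combined over simultaneous
    merges; low probability = strong evidence the merge would cross the
    barcode gap, i.e. stopping at h is right) and (b) the relative gap
    width W = (next height - h)/h.  The score is the mean of the two ranks;
    ties prefer fewer MOTUs, then the lower threshold.
    """
    n = len(matrix.ids)
    if n < 3:
        raise ValueError("need at least 3 sequences")
    rng = np.random.default_rng(seed)
    vals = matrix.values.copy()
    finite_max = np.nanmax(np.where(np.isfinite(vals), vals, np.nan))
    big = (finite_max if np.isfinite(finite_max) else 1.0) * 10 + 10.0
    vals[np.isinf(vals)] = big  # saturated pairs: merge last, far beyond data
    iu = np.triu_indices(n, k=1)
    Z = linkage(vals[iu], method="single")
    heights = Z[:, 2]
    distinct = np.unique(heights)

    # Reconstruct cluster memberships merge by merge.
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    merge_members: list[tuple[list[int], list[int]]] = []
    for k, (a, b, h, _) in enumerate(Z):
        ga, gb = clusters.pop(int(a)), clusters.pop(int(b))
        merge_members.append((ga, gb))
        clusters[n + k] = ga + gb

    def _within(idx: list[int]) -> np.ndarray:
        if len(idx) < 2:
            return np.empty(0)
        sub = matrix.values[np.ix_(idx, idx)]
        w = sub[np.triu_indices(len(idx), k=1)]
        return w[np.isfinite(w)]

    def _between(a: list[int], b: list[int]) -> np.ndarray:
        cross = matrix.values[np.ix_(a, b)].ravel()
        return cross[np.isfinite(cross)]

    rows_raw = []
    for hi, h in enumerate(distinct):
        # candidate partition: cut the dendrogram at height h (inclusive)
        next_h = distinct[hi + 1] if hi + 1 < distinct.size else None
        n_motus = n - int(np.sum(heights <= h))
        if next_h is None:
            prob, W = 1.0, 0.0
        else:
            W = float((next_h - h) / h) if h > 0 else float("inf")
            pvals = []
            for k in np.flatnonzero(heights == next_h):
                ga, gb = merge_members[k]
                pvals.append(
                    _perm_pvalue(
                        np.concatenate([_within(ga), _within(gb)]) if (len(ga) > 1 or len(gb) > 1) else np.empty(0),
                        _between(ga, gb),
                        rng,
                        n_permutations,
                    )
                )
            stat = -2.0 * np.sum(np.log(pvals))
            prob = max(
                float(chi2.sf(stat, 2 * len(pvals))), 3.0 / (1 + n_permutations)
            )
        rows_raw.append((float(h), n_motus, prob, W))

    probs = np.array([r[2] for r in rows_raw])
    Ws = np.array([r[3] for r in rows_raw])
    prob_ranks = rankdata(probs, method="min")
    gap_ranks = rankdata(-Ws, method="min")
    rows = [
        AsapScoreRow(h, m, p, w, int(pr), int(gr), (pr + gr) / 2.0)
        for (h, m, p, w), pr, gr in zip(rows_raw, prob_ranks, gap_ranks)
    ]
    best = min(rows, key=lambda r: (r.asap_score, r.gap_rank, r.n_motus, r.threshold))
    part = single_linkage_threshold(matrix, best.threshold)
    part.method = "asap"
    part.params = {
        "threshold": best.threshold,
        "asap_score": best.asap_score,
        "seed": seed,
        "n_permutations": n_permutations,
    }
    return rows, part
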
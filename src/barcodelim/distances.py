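"""Kimura 2-parameter distances and barcode-gap statistics.

The K2P model corrects observed divergence separately for transitions
(A<->G, C<->T; proportion P) and transversions (proportion Q):

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

Sites where either sequence carries a gap, 'N', '?' or any other ambiguity
code are excluded pairwise (pairwise deletion), so every pair is compared
over its own set of n_valid unambiguous sites.  When the log arguments are
non-positive the distance is saturated and reported as the SATURATED
sentinel (treated as "infinitely distant": excluded from means/minima and
never merged by clustering).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .io_formats import AlignedMatrix, Taxon

__all__ = [
    "SATURATED",
    "PairwiseDistance",
    "DistanceMatrix",
    "SpeciesDistanceSummary",
    "ThresholdEvalResult",
    "k2p_distance",
    "distance_matrix",
    "summarize_levels",
    "species_summaries",
    "evaluate_threshold",
    "distance_histogram",
    "encode_alignment",
    "fmt_pct",
]

#: Sentinel for pairs beyond the K2P correction's domain.
SATURATED = math.inf

_CODE = np.full(256, 4, dtype=np.uint8)
for i, base in enumerate("ACGT"):
    _CODE[ord(base)] = i
_PURINE = np.array([True, False, True, False, False])  # A, C, G, T, other


def fmt_pct(x: float, decimals: int = 2) -> str:
    """Format a proportion as a percentage string, round-half-away-from-zero."""
    scaled = x * 100.0 * 10**decimals
    rounded = math.copysign(math.floor(abs(scaled) + 0.5), scaled)
    return f"{rounded / 10**decimals:.{decimals}f}"


def encode_alignment(alignment: AlignedMatrix) -> np.ndarray:
    """uint8 matrix (n_records, alignment_length): A,C,G,T -> 0..3, other -> 4."""
    arr = np.frombuffer(
        "".join(r.sequence for r in alignment.records).encode("ascii"), dtype=np.uint8
    ).reshape(len(alignment), alignment.alignment_length)
    return _CODE[arr]


@dataclass(frozen=True)
class PairwiseDistance:
    """P/Q site proportions, valid-site count and the K2P distance for one pair."""

    P: float
    Q: float
    n_valid: int
    d: float  # substitutions/site, or SATURATED

    @property
    def saturated(self) -> bool:
        return math.isinf(self.d)


def _k2p_from_pq(P: float, Q: float) -> float:
    a = 1.0 - 2.0 * P - Q
    b = 1.0 - 2.0 * Q
    if a <= 0.0 or b <= 0.0:
        return SATURATED
    return -0.5 * math.log(a) - 0.25 * math.log(b)


def k2p_distance(seq_a: str, seq_b: str, min_valid_sites: int = 1) -> PairwiseDistance:
    """K2P distance between two aligned sequences under pairwise deletion."""
    if len(seq_a) != len(seq_b):
        raise ValueError(f"aligned lengths differ: {len(seq_a)} vs {len(seq_b)}")
    if min_valid_sites < 1:
        raise ValueError("min_valid_sites must be >= 1")
    a = _CODE[np.frombuffer(seq_a.upper().encode("ascii"), dtype=np.uint8)]
    b = _CODE[np.frombuffer(seq_b.upper().encode("ascii"), dtype=np.uint8)]
    valid = (a < 4) & (b < 4)
    n_valid = int(valid.sum())
    if n_valid < min_valid_sites:
        raise ValueError(
            f"only {n_valid} jointly unambiguous sites (< {min_valid_sites}) for this pair"
        )
    diff = valid & (a != b)
    ts = int((diff & (_PURINE[a] == _PURINE[b])).sum())
    tv = int(diff.sum()) - ts
    P, Q = ts / n_valid, tv / n_valid
    return PairwiseDistance(P=P, Q=Q, n_valid=n_valid, d=_k2p_from_pq(P, Q))


@dataclass
class DistanceMatrix:
    """Symmetric K2P distance matrix with per-pair valid-site counts."""

    ids: list[str]
    values: np.ndarray  # (n, n) float; SATURATED entries are +inf
    n_valid: np.ndarray  # (n, n) int
    min_valid_sites: int

    def __post_init__(self) -> None:
        self._index = {sid: i for i, sid in enumerate(self.ids)}

    def get(self, id_a: str, id_b: str) -> float:
        return float(self.values[self._index[id_a], self._index[id_b]])

    def __len__(self) -> int:
        return len(self.ids)

    def submatrix(self, keep_ids: Iterable[str]) -> "DistanceMatrix":
        keep = [sid for sid in self.ids if sid in set(keep_ids)]
        idx = np.array([self._index[s] for s in keep], dtype=int)
        return DistanceMatrix(
            keep, self.values[np.ix_(idx, idx)], self.n_valid[np.ix_(idx, idx)],
            self.min_valid_sites,
        )

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances in scipy condensed order."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def pair_iter(self):
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                yield self.ids[i], self.ids[j], float(self.values[i, j])

    def write_tsv(self, path, header_lines: list[str] | None = None) -> None:
        """Lower-triangle TSV with an id header row; 6 significant digits."""
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            fh.write("seq_id\t" + "\t".join(self.ids) + "\n")
            for i, sid in enumerate(self.ids):
                cells = []
                for j in range(i):
                    v = self.values[i, j]
                    cells.append("SATURATED" if math.isinf(v) else f"{v:.6g}")
                fh.write(sid + ("\t" + "\t".join(cells) if cells else "") + "\n")


def distance_matrix(alignment: AlignedMatrix, min_valid_sites: int = 300) -> DistanceMatrix:
    """All-pairs K2P matrix; errors (naming the pair) if any pair's overlap is too small."""
    if len(alignment) < 2:
        raise ValueError("need at least 2 records for a distance matrix")
    codes = encode_alignment(alignment)
    n = codes.shape[0]
    valid = codes < 4
    purine = _PURINE[codes]
    values = np.zeros((n, n), dtype=float)
    n_valid = np.zeros((n, n), dtype=np.int64)
    np.fill_diagonal(n_valid, valid.sum(axis=1))
    for i in range(n - 1):
        v = valid[i] & valid[i + 1 :]
        nv = v.sum(axis=1)
        diff = v & (codes[i] != codes[i + 1 :])
        ts = (diff & (purine[i] == purine[i + 1 :])).sum(axis=1)
        tot = diff.sum(axis=1)
        if (nv < min_valid_sites).any():
            j = i + 1 + int(np.argmax(nv < min_valid_sites))
            raise ValueError(
                f"pair ({alignment.ids[i]}, {alignment.ids[j]}): only "
                f"{int(nv[j - i - 1])} jointly unambiguous sites (< {min_valid_sites})"
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            P = ts / nv
            Q = (tot - ts) / nv
            a = 1.0 - 2.0 * P - Q
            b = 1.0 - 2.0 * Q
            d = np.where(
                (a > 0) & (b > 0), -0.5 * np.log(np.maximum(a, 1e-300)) - 0.25 * np.log(np.maximum(b, 1e-300)), np.inf
            )
        values[i, i + 1 :] = d
        values[i + 1 :, i] = d
        n_valid[i, i + 1 :] = nv
        n_valid[i + 1 :, i] = nv
    return DistanceMatrix(list(alignment.ids), values, n_valid, min_valid_sites)


# ---------------------------------------------------------------------------
# Pooled-level summaries
# ---------------------------------------------------------------------------

def _pool_stats(pool: np.ndarray) -> dict:
    finite = pool[np.isfinite(pool)]
    n_sat = int(np.isinf(pool).sum())
    if finite.size == 0:
        return {"n_pairs": int(pool.size), "n_saturated": n_sat,
                "mean": None, "min": None, "max": None}
    return {
        "n_pairs": int(pool.size),
        "n_saturated": n_sat,
        "mean": float(finite.mean()),
        "min": float(finite.min()),
        "max": float(finite.max()),
    }


def summarize_levels(matrix: DistanceMatrix, meta: Mapping[str, Taxon]) -> dict:
    """Mean/min/max of the intra-species, intra-genus (between species) and
    intra-subfamily (between genera) distance pools.

    Pairs lacking a genus or subfamily label are skipped at that level;
    pairs in none of the three pools fall into "between_subfamily".
    Saturated pairs are excluded from the statistics and counted.
    """
    n = len(matrix.ids)
    species = np.array([meta[s].species for s in matrix.ids], dtype=object)
    genus = np.array([meta[s].genus for s in matrix.ids], dtype=object)
    subfam = np.array([meta[s].subfamily for s in matrix.ids], dtype=object)
    iu = np.triu_indices(n, k=1)
    d = matrix.values[iu]
    same_sp = species[iu[0]] == species[iu[1]]
    same_gen = (genus[iu[0]] == genus[iu[1]]) & (genus[iu[0]] != "")
    same_sub = (subfam[iu[0]] == subfam[iu[1]]) & (subfam[iu[0]] != "")
    pools = {
        "within_species": d[same_sp],
        "within_genus": d[~same_sp & same_gen],
        "within_subfamily": d[~same_sp & ~same_gen & same_sub],
        "between_subfamily": d[~same_sp & ~same_gen & ~same_sub],
    }
    return {level: _pool_stats(pool) for level, pool in pools.items()}


@dataclass(frozen=True)
class SpeciesDistanceSummary:
    species: str
    n_seqs: int
    max_intra: float | None  # None = undefined (singleton)
    mean_intra: float | None
    nearest_neighbor: str | None
    min_inter_nn: float | None
    barcode_gap: float | None  # min_inter_nn - max_intra; None when max_intra undefined


def species_summaries(
    matrix: DistanceMatrix, meta: Mapping[str, Taxon]
) -> list[SpeciesDistanceSummary]:
    """Per-morphospecies divergence summary and nearest-neighbour statistics.

    The nearest neighbour is the other species minimising the minimum
    between-species distance (ties broken lexicographically by label).
    """
    species = np.array([meta[s].species for s in matrix.ids], dtype=object)
    labels = sorted(set(species))
    idx_by_sp = {sp: np.flatnonzero(species == sp) for sp in labels}
    out = []
    for sp in labels:
        idx = idx_by_sp[sp]
        n_seqs = len(idx)
        max_intra = mean_intra = None
        if n_seqs > 1:
            sub = matrix.values[np.ix_(idx, idx)][np.triu_indices(n_seqs, k=1)]
            finite = sub[np.isfinite(sub)]
            if finite.size:
                max_intra = float(finite.max())
                mean_intra = float(finite.mean())
        nn = None
        min_inter = None
        for other in labels:
            if other == sp:
                continue
            cross = matrix.values[np.ix_(idx, idx_by_sp[other])]
            finite = cross[np.isfinite(cross)]
            if finite.size == 0:
                continue
            m = float(finite.min())
            if min_inter is None or m < min_inter or (m == min_inter and other < nn):
                min_inter, nn = m, other
        gap = None
        if max_intra is not None and min_inter is not None:
            gap = min_inter - max_intra
        out.append(
            SpeciesDistanceSummary(sp, n_seqs, max_intra, mean_intra, nn, min_inter, gap)
        )
    return out


@dataclass(frozen=True)
class ThresholdEvalResult:
    t: float
    n_species: int
    n_species_defined: int
    fraction_defined: float
    n_intra_below: int  # non-singleton species with max_intra < t
    n_inter_above: int  # species with min_inter_nn > t


def evaluate_threshold(
    summaries: list[SpeciesDistanceSummary],
    t: float = 0.03,
    include_singletons: bool = True,
) -> ThresholdEvalResult:
    """Count species "accurately defined" by a fixed distance threshold t.

    A species is defined at t iff its maximum intraspecific distance is
    below t (vacuously true for singletons when include_singletons) AND its
    minimum distance to the nearest neighbour exceeds t.  With
    include_singletons=False, singletons are removed from both numerator
    and denominator (sensitivity variant).
    """
    if t <= 0:
        raise ValueError("threshold t must be positive")
    rows = summaries if include_singletons else [s for s in summaries if s.n_seqs > 1]
    n_def = 0
    n_intra_below = 0
    n_inter_above = 0
    for s in rows:
        intra_ok = s.n_seqs == 1 or (s.max_intra is not None and s.max_intra < t)
        inter_ok = s.min_inter_nn is not None and s.min_inter_nn > t
        if s.n_seqs > 1 and s.max_intra is not None and s.max_intra < t:
            n_intra_below += 1
        if inter_ok:
            n_inter_above += 1
        if intra_ok and inter_ok:
            n_def += 1
    n = len(rows)
    return ThresholdEvalResult(
        t=t,
        n_species=n,
        n_species_defined=n_def,
        fraction_defined=(n_def / n) if n else 0.0,
        n_intra_below=n_intra_below,
        n_inter_above=n_inter_above,
    )


def threshold_curve(
    summaries: list[SpeciesDistanceSummary],
    grid: Iterable[float],
    include_singletons: bool = True,
) -> tuple[list[ThresholdEvalResult], ThresholdEvalResult]:
    """Evaluate a grid of thresholds and expose the maximising one."""
    results = [evaluate_threshold(summaries, t, include_singletons) for t in grid]
    best = max(results, key=lambda r: (r.fraction_defined, -r.t))
    return results, best


def distance_histogram(
    matrix: DistanceMatrix, meta: Mapping[str, Taxon], bin_width: float
) -> dict:
    """Binned intra- and inter-specific pair counts over [0, max finite distance].

    Returns {"edges": ndarray, "intra": counts, "inter": counts}; counts sum
    to the respective (finite) pool sizes.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n = len(matrix.ids)
    species = np.array([meta[s].species for s in matrix.ids], dtype=object)
    iu = np.triu_indices(n, k=1)
    d = matrix.values[iu]
    same = species[iu[0]] == species[iu[1]]
    intra = d[same & np.isfinite(d)]
    inter = d[~same & np.isfinite(d)]
    finite_all = np.concatenate([intra, inter])
    if finite_all.size == 0:
        edges = np.array([0.0, bin_width])
    else:
        top = max(float(finite_all.max()), bin_width)
        edges = np.arange(0.0, top + bin_width, bin_width)
        if edges[-1] <= top:
            edges = np.append(edges, edges[-1] + bin_width)
    return {
        "edges": edges,
        "intra": np.histogram(intra, bins=edges)[0] if intra.size else np.zeros(len(edges) - 1, int),
        "inter": np.histogram(inter, bins=edges)[0] if inter.size else np.zeros(len(edges) - 1, int),
    }
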
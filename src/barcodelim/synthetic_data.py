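"""Seeded generators of synthetic barcode datasets and two-rate gene trees.

The alignment generator emulates the statistical structure of a typical
single-marker barcode study of a diverse beetle group: strongly skewed
per-species sampling (~44% singletons, a long geometric tail capped near
55 sequences), within-species divergence centred near 2.9%, between-species
divergence near 22%, with optional deep-split lineages (one morphospecies
hiding two divergent clusters) and merge pairs (two labels on what is
genetically one cluster).  Mutations follow the K2P process itself — a
Poisson number of substitution events per branch, transition-biased with
ratio kappa — so the distance estimator is exactly matched to the
generator; multiple hits occur, so realized K2P estimates sit slightly
below the event counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .io_formats import AlignedMatrix, Partition, SequenceRecord, Taxon

__all__ = ["SyntheticConfig", "generate_dataset", "generate_ptp_tree"]

_BASES = np.array(list("ACGT"))
# transition partner of A,C,G,T and the two transversion partners
_TS = np.array([2, 3, 0, 1])  # A<->G, C<->T
_TV = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])


@dataclass
class SamplingRule:
    """Per-species sequence counts: fixed n, or a singleton-heavy mixture."""

    fixed: int | None = None
    fraction_singletons: float = 0.44
    geometric_p: float = 0.14  # tail for non-singleton species (mean ~ 1 + 1/p)
    max_per_species: int = 55

    def draw(self, rng: np.random.Generator) -> int:
        if self.fixed is not None:
            return self.fixed
        if rng.random() < self.fraction_singletons:
            return 1
        return min(1 + int(rng.geometric(self.geometric_p)), self.max_per_species)


@dataclass
class SyntheticConfig:
    n_species: int = 20
    seqs_per_species: SamplingRule = field(default_factory=SamplingRule)
    seq_length: int = 658
    intra_divergence: float = 0.029
    inter_divergence: float = 0.22
    kappa: float = 2.0
    deep_split_fraction: float = 0.0
    merge_pair_count: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.intra_divergence < self.inter_divergence < 0.75):
            raise ValueError("need 0 < intra_divergence < inter_divergence < 0.75")
        if self.seq_length < 300:
            raise ValueError("seq_length must be >= 300")
        if 2 * self.merge_pair_count > self.n_species:
            raise ValueError("merge_pair_count too large for n_species")

    def to_dict(self) -> dict:
        return asdict(self)


def _mutate(seq: np.ndarray, n_events: int, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Apply n substitution events, site-uniform, transition prob kappa/(kappa+2)."""
    out = seq.copy()
    if n_events == 0:
        return out
    sites = rng.integers(0, len(seq), size=n_events)
    is_ts = rng.random(n_events) < kappa / (kappa + 2.0)
    for site, ts in zip(sites, is_ts):
        cur = out[site]
        out[site] = _TS[cur] if ts else _TV[cur, rng.integers(2)]
    return out


def _poisson_events(rng: np.random.Generator, expected_div: float, length: int) -> int:
    return int(rng.poisson(expected_div * length))


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[AlignedMatrix, dict[str, Taxon], Partition, str]:
    """Generate (alignment, metadata, truth partition, truth tree newick).

    One ancestral sequence per species, mutated from a common root at half
    the target between-species divergence (star phylogeny), so expected
    pairwise inter-species divergence ~ inter_divergence; each sampled
    sequence is mutated from its ancestor at half the intra target.  Deep
    splits add a second, inter-level lineage under one species label (truth
    partition splits it); merge pairs generate two species labels at
    intra-level divergence (truth partition joins them).  Byte-reproducible
    from the seed.
    """
    rng = np.random.default_rng(config.seed)
    L = config.seq_length
    root = rng.integers(0, 4, size=L)

    n_deep = int(round(config.deep_split_fraction * config.n_species))
    species_names = [f"sp{k + 1:03d}" for k in range(config.n_species)]
    deep_species = set(species_names[:n_deep])
    # merge pairs taken from the tail so they never overlap deep splits
    merge_pairs = [
        (species_names[-(2 * i + 2)], species_names[-(2 * i + 1)])
        for i in range(config.merge_pair_count)
    ]
    merge_partner = {b: a for a, b in merge_pairs}

    # one generating lineage = one truth class
    lineages: list[tuple[str, str, np.ndarray]] = []  # (lineage_id, species, ancestor)
    for sp in species_names:
        if sp in merge_partner:
            # partner of an existing lineage: ancestor drawn at intra-level
            src = next(anc for lid, s, anc in lineages if s == merge_partner[sp])
            anc = _mutate(src, _poisson_events(rng, config.intra_divergence, L), config.kappa, rng)
            lineages.append((f"{merge_partner[sp]}+{sp}", sp, anc))
        else:
            # ancestors sit at (inter - intra)/2 events/site from the root, so a
            # between-species LEAF pair (ancestor paths + two tip branches of
            # intra/2 each) expects inter_divergence events/site in total
            anc_div = (config.inter_divergence - config.intra_divergence) / 2.0
            anc = _mutate(root, _poisson_events(rng, anc_div, L), config.kappa, rng)
            lineages.append((sp, sp, anc))
            if sp in deep_species:
                anc2 = _mutate(
                    anc, _poisson_events(rng, 2.0 * anc_div, L), config.kappa, rng
                )
                lineages.append((f"{sp}~B", sp, anc2))

    # merged lineages share one truth class with their partner
    truth_class = {}
    for lid, sp, _ in lineages:
        truth_class[lid] = lid.split("+")[0] if "+" in lid else lid

    records: list[SequenceRecord] = []
    meta: dict[str, Taxon] = {}
    assignment: dict[str, str] = {}
    tree_parts: list[str] = []
    by_species: dict[str, list[tuple[str, np.ndarray]]] = {}
    for lid, sp, anc in lineages:
        by_species.setdefault(sp, []).append((lid, anc))

    seq_counter = 0
    for k, sp in enumerate(species_names):
        lins = by_species[sp]
        n_seqs = config.seqs_per_species.draw(rng)
        if len(lins) > 1:
            n_seqs = max(n_seqs, 2)  # a deep split needs a member on each side
        genus = f"gen{(k % max(1, config.n_species // 3)) + 1:02d}"
        leaf_strs: dict[str, list[str]] = {lid: [] for lid, _ in lins}
        for j in range(n_seqs):
            lid, anc = lins[j % len(lins)]
            seq_counter += 1
            sid = f"seq{seq_counter:04d}"
            seq = _mutate(
                anc, _poisson_events(rng, config.intra_divergence / 2.0, L), config.kappa, rng
            )
            records.append(
                SequenceRecord(
                    sid,
                    "".join(_BASES[seq]),
                    species=sp,
                    genus=genus,
                    subfamily="synthfam",
                    locality=f"site{rng.integers(1, 6)}",
                )
            )
            meta[sid] = Taxon(sp, genus, "synthfam", "")
            assignment[sid] = truth_class[lid]
            leaf_strs[lid].append(f"{sid}:{config.intra_divergence / 2.0:.6f}")
        for lid, leaves in leaf_strs.items():
            if not leaves:
                continue
            anc_b = (config.inter_divergence - config.intra_divergence) / 2.0
            if len(leaves) == 1:
                tree_parts.append(f"{leaves[0].split(':')[0]}:{anc_b:.6f}")
            else:
                tree_parts.append("(" + ",".join(leaves) + f"):{anc_b:.6f}")
    newick = "(" + ",".join(tree_parts) + "):0.0;"
    alignment = AlignedMatrix(records)
    truth = Partition(method="truth", params=config.to_dict(), assignment=assignment)
    return alignment, meta, truth, newick


def generate_ptp_tree(
    n_species: int,
    leaves_per_species: int,
    mean_between: float = 1.0,
    mean_within: float = 0.02,
    seed: int = 0,
) -> tuple[str, Partition]:
    """Random rooted binary tree with two exponential branch-length classes.

    The species backbone is built by random sequential joining with edge
    lengths ~ Exponential(mean_between); each species carries a random
    coalescent-shaped subtree with edge lengths ~ Exponential(mean_within).
    Returns (newick, truth partition by species).
    """
    if not mean_between > mean_within > 0:
        raise ValueError("need mean_between > mean_within > 0")
    rng = np.random.default_rng(seed)

    def _join(subtrees: list[str], mean: float) -> str:
        while len(subtrees) > 1:
            i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
            b = subtrees.pop(j)
            a = subtrees.pop(i)
            la, lb = rng.exponential(mean), rng.exponential(mean)
            subtrees.append(f"({a}:{la:.8f},{b}:{lb:.8f})")
        return subtrees[0]

    assignment = {}
    species_subtrees = []
    for k in range(n_species):
        labels = [f"sp{k + 1:03d}_{j + 1:02d}" for j in range(leaves_per_species)]
        for lab in labels:
            assignment[lab] = f"sp{k + 1:03d}"
        if len(labels) == 1:
            species_subtrees.append(labels[0])
        else:
            species_subtrees.append(_join(list(labels), mean_within))
    if n_species == 1:
        newick = f"({species_subtrees[0]}:{rng.exponential(mean_within):.8f});"
    else:
        newick = _join(species_subtrees, mean_between) + ";"
    truth = Partition(
        method="truth",
        params={
            "n_species": n_species,
            "leaves_per_species": leaves_per_species,
            "mean_between": mean_between,
            "mean_within": mean_within,
            "seed": seed,
        },
        assignment=assignment,
    )
    return newick, truth
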
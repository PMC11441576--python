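import numpy as np
import pytest

from barcodelim.distances import DistanceMatrix
from barcodelim.io_formats import AlignedMatrix, SequenceRecord, Taxon
from barcodelim.synthetic_data import SamplingRule, SyntheticConfig, generate_dataset


def make_matrix(ids, pairs, default=0.2):
    """Symmetric DistanceMatrix from {(a, b): d} with a default elsewhere."""
    n = len(ids)
    idx = {s: i for i, s in enumerate(ids)}
    vals = np.full((n, n), default, dtype=float)
    np.fill_diagonal(vals, 0.0)
    for (a, b), d in pairs.items():
        vals[idx[a], idx[b]] = vals[idx[b], idx[a]] = d
    return DistanceMatrix(list(ids), vals, np.full((n, n), 658, dtype=np.int64), 1)


def make_alignment(seqs, species=None):
    """AlignedMatrix from {seq_id: sequence} (insertion order preserved)."""
    species = species or {}
    return AlignedMatrix(
        [SequenceRecord(sid, seq, species=species.get(sid, "")) for sid, seq in seqs.items()]
    )


@pytest.fixture
def ten_species_dataset():
    """Clean 10-species dataset: intra 1%, inter 10%, 3 sequences each."""
    cfg = SyntheticConfig(
        n_species=10,
        seqs_per_species=SamplingRule(fixed=3),
        intra_divergence=0.01,
        inter_divergence=0.10,
        seed=42,
    )
    return generate_dataset(cfg)


@pytest.fixture
def taxa_two_species():
    return {
        "s1": Taxon("spA", "gen1", "fam1"),
        "s2": Taxon("spA", "gen1", "fam1"),
        "s3": Taxon("spB", "gen1", "fam1"),
        "s4": Taxon("spB", "gen1", "fam1"),
    }
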
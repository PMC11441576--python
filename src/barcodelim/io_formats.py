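"""Readers/writers for the external formats the pipeline consumes and emits.

FASTA, newick, metadata TSV, MOTU-partition TSV. Parsing is deliberately
permissive about ambiguity characters ('N', '?', '-'); their semantics are
decided downstream by the QC and distance layers.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO

# IUPAC nucleotide codes, gap, and '?' (missing data as written by some
# alignment editors).  Anything else is a hard I/O error.
IUPAC_CHARS = frozenset("ACGTRYSWKMBDHVN-?")

__all__ = [
    "SequenceRecord",
    "AlignedMatrix",
    "Partition",
    "Taxon",
    "read_fasta",
    "write_fasta",
    "read_metadata",
    "read_partition_tsv",
    "write_partition_tsv",
    "read_newick",
    "IUPAC_CHARS",
]


class FormatError(ValueError):
    """Raised on malformed input files."""


class Taxon(NamedTuple):
    species: str
    genus: str = ""
    subfamily: str = ""
    locality: str = ""


@dataclass(frozen=True)
class SequenceRecord:
    """One identified barcode sequence with its taxonomy metadata."""

    seq_id: str
    sequence: str
    species: str = ""
    genus: str = ""
    subfamily: str = ""
    locality: str = ""

    def __post_init__(self) -> None:
        if not self.seq_id or re.search(r"\s", self.seq_id):
            raise FormatError(f"invalid seq_id {self.seq_id!r}: empty or contains whitespace")
        if not self.sequence:
            raise FormatError(f"sequence for {self.seq_id!r} is empty")
        bad = set(self.sequence) - IUPAC_CHARS
        if bad:
            pos = next(i for i, c in enumerate(self.sequence) if c in bad)
            raise FormatError(
                f"sequence {self.seq_id!r} has non-IUPAC character {self.sequence[pos]!r} at position {pos}"
            )

    @property
    def ungapped(self) -> str:
        """Sequence with alignment gaps and '?' removed."""
        return self.sequence.replace("-", "").replace("?", "")


@dataclass
class AlignedMatrix:
    """An ordered multiple alignment of SequenceRecords (input order preserved)."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise FormatError("alignment has no records")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) != 1:
            raise FormatError(f"unequal aligned lengths: {sorted(lengths)}")
        ids = [r.seq_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise FormatError(f"duplicate seq_id {dup!r} in alignment")

    @property
    def alignment_length(self) -> int:
        return len(self.records[0].sequence)

    @property
    def ids(self) -> list[str]:
        return [r.seq_id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def species_map(self) -> dict[str, str]:
        return {r.seq_id: r.species for r in self.records}

    def taxon_map(self) -> dict[str, Taxon]:
        return {
            r.seq_id: Taxon(r.species, r.genus, r.subfamily, r.locality) for r in self.records
        }

    def subset(self, keep_ids: Iterable[str]) -> "AlignedMatrix":
        keep = set(keep_ids)
        return AlignedMatrix([r for r in self.records if r.seq_id in keep])

    @classmethod
    def from_sequences(
        cls,
        pairs: Sequence[tuple[str, str]],
        meta: Mapping[str, Taxon] | None = None,
    ) -> "AlignedMatrix":
        """Assemble an alignment from (seq_id, sequence) pairs plus optional taxonomy."""
        records = []
        for seq_id, seq in pairs:
            tx = meta.get(seq_id) if meta else None
            if meta is not None and tx is None:
                raise FormatError(f"seq_id {seq_id!r} missing from metadata")
            records.append(
                SequenceRecord(
                    seq_id,
                    seq,
                    species=tx.species if tx else "",
                    genus=tx.genus if tx else "",
                    subfamily=tx.subfamily if tx else "",
                    locality=tx.locality if tx else "",
                )
            )
        return cls(records)


@dataclass
class Partition:
    """A MOTU assignment produced by one delimitation method.

    MOTU labels are opaque: two partitions are equivalent iff they induce
    the same set-partition of seq_ids, regardless of labelling.
    """

    method: str
    params: dict = field(default_factory=dict)
    assignment: dict[str, str] = field(default_factory=dict)

    def classes(self) -> frozenset[frozenset[str]]:
        groups: dict[str, set[str]] = {}
        for sid, motu in self.assignment.items():
            groups.setdefault(motu, set()).add(sid)
        return frozenset(frozenset(g) for g in groups.values())

    def n_motus(self) -> int:
        return len(set(self.assignment.values()))

    def same_partition(self, other: "Partition") -> bool:
        return self.classes() == other.classes()

    def relabel_by_smallest_member(self) -> "Partition":
        """Deterministic labels: each MOTU named after its lexicographically smallest member."""
        new = {}
        for cls_ in self.classes():
            label = min(cls_)
            for sid in cls_:
                new[sid] = label
        return Partition(self.method, dict(self.params), new)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Parse a multi-record FASTA into ordered (seq_id, sequence) pairs.

    The id is the first whitespace-delimited header token.  Sequences are
    upper-cased and RNA 'U' is normalized to 'T'.  Duplicate ids, empty
    files and non-IUPAC characters are hard errors.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        bad = set(seq) - IUPAC_CHARS
        if bad:
            pos = next(i for i, c in enumerate(seq) if c in bad)
            raise FormatError(
                f"record {rec.id!r}: non-IUPAC character {seq[pos]!r} at position {pos}"
            )
        if not seq:
            raise FormatError(f"record {rec.id!r} has an empty sequence")
        pairs.append((rec.id, seq))
    if not pairs:
        raise FormatError(f"no FASTA records found in {path}")
    return pairs


def write_fasta(path: str | Path, pairs: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for seq_id, seq in pairs:
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Metadata TSV
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> dict[str, Taxon]:
    """Read the specimen table: TSV with at least ``seq_id`` and ``species`` columns.

    ``genus``, ``subfamily`` and ``locality`` are optional and default to "".
    Unknown columns are ignored.  '#'-prefixed lines are comments.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    for col in ("seq_id", "species"):
        if col not in df.columns:
            raise FormatError(f"metadata file {path} lacks required column {col!r}")
    if df["seq_id"].duplicated().any():
        dup = df.loc[df["seq_id"].duplicated(), "seq_id"].iloc[0]
        raise FormatError(f"metadata file {path}: repeated seq_id {dup!r}")
    if (df["species"].str.strip() == "").any():
        sid = df.loc[df["species"].str.strip() == "", "seq_id"].iloc[0]
        raise FormatError(f"metadata file {path}: missing species for {sid!r}")
    out: dict[str, Taxon] = {}
    for _, row in df.iterrows():
        out[row["seq_id"]] = Taxon(
            species=row["species"],
            genus=row.get("genus", ""),
            subfamily=row.get("subfamily", ""),
            locality=row.get("locality", ""),
        )
    return out


# ---------------------------------------------------------------------------
# Partition TSV
# ---------------------------------------------------------------------------

def read_partition_tsv(
    path: str | Path, dataset_ids: Iterable[str] | None = None
) -> Partition:
    """Read an externally produced two-column (seq_id, motu_label) table.

    A header row is auto-detected: if the first row's first field occurs in
    ``dataset_ids`` it is data, otherwise it is treated as a header.  The
    method label records the file stem, e.g. ``external:bins``.
    """
    path = Path(path)
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}: expected 2 tab-separated columns, got {line!r}")
            rows.append(fields[:2])
    if not rows:
        raise FormatError(f"partition file {path} is empty")
    known = set(dataset_ids) if dataset_ids is not None else None
    first_is_header = (
        rows[0][0].lower() in {"seq_id", "id", "sequence_id"}
        if known is None
        else rows[0][0] not in known
    )
    if first_is_header:
        rows = rows[1:]
    if not rows:
        raise FormatError(f"partition file {path} has a header but no data rows")
    assignment: dict[str, str] = {}
    for sid, motu in rows:
        if sid in assignment:
            raise FormatError(f"partition file {path}: seq_id {sid!r} assigned twice")
        assignment[sid] = motu
    return Partition(method=f"external:{path.stem}", params={"path": str(path)}, assignment=assignment)


def write_partition_tsv(path: str | Path, partition: Partition) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tmotu\n")
        for sid in sorted(partition.assignment):
            fh.write(f"{sid}\t{partition.assignment[sid]}\n")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def read_newick(path_or_string: str | Path) -> dendropy.Tree:
    """Read a single rooted newick tree (branch lengths optional at parse time).

    Zero-length branches are permitted but flagged with a warning; validity
    requirements specific to PTP (all lengths present and positive, leaf
    labels matching the dataset) are enforced at delimitation time.
    """
    s = str(path_or_string)
    if "(" in s:  # a bare newick string rather than a path
        text = s
    else:
        text = Path(s).read_text()
    if text.count("(") != text.count(")"):
        raise FormatError("unbalanced parentheses in newick input")
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"could not parse newick: {exc}") from exc
    n_zero = sum(
        1 for e in tree.preorder_edge_iter() if e.length is not None and e.length == 0
    )
    if n_zero:
        warnings.warn(f"newick tree contains {n_zero} zero-length branch(es)", stacklevel=2)
    return tree
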
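"""Method-vs-morphology decision layer.

Compares the MOTU partitions produced by several delimitation methods
against the morphospecies labels, classifies each morphospecies as
congruent / taxonomic warning (split or merge) / ambiguous under quorum
rules, and computes the match-rate and dataset-composition summary.

Default quorums follow the usual congruence convention for six-method
barcode studies: a morphospecies is congruent when at least 3 methods
place all its sequences alone in a single MOTU; it is flagged as a
warning when at least 4 methods split it into multiple MOTUs (possible
cryptic diversity) or at least 4 methods merge it with another
morphospecies (possible misidentification or synonymy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import pandas as pd

from .distances import fmt_pct
from .io_formats import Partition

__all__ = [
    "ConsensusRow",
    "ConsensusReport",
    "tabulate",
    "classify",
    "summarize",
    "load_reference_warning_table",
]


@dataclass
class ConsensusRow:
    species: str
    n_seqs: int
    per_method_motus: dict[str, int] = field(default_factory=dict)
    per_method_merged: dict[str, bool] = field(default_factory=dict)
    status: str | None = None  # congruent | warning_split | warning_merge | ambiguous
    split_flag: bool = False
    merge_flag: bool = False


@dataclass
class ConsensusReport:
    rows: list[ConsensusRow]
    n_congruent: int
    n_warnings: int
    n_ambiguous: int
    match_rate: float
    method_motu_totals: dict[str, int]
    composition: dict[str, int]  # n_singleton / n_two / n_multi species

    @property
    def n_species(self) -> int:
        return len(self.rows)

    def match_rate_pct(self) -> str:
        return fmt_pct(self.match_rate, 1)


def tabulate(
    partitions: list[Partition], morphospecies: Mapping[str, str]
) -> list[ConsensusRow]:
    """Per species and method: number of distinct MOTUs touched, and whether
    any of those MOTUs also contains another species' sequence."""
    if len(partitions) < 2:
        raise ValueError("need at least 2 method partitions")
    id_sets = [set(p.assignment) for p in partitions]
    base = id_sets[0]
    for p, ids in zip(partitions[1:], id_sets[1:]):
        if ids != base:
            diff = sorted(ids.symmetric_difference(base))
            raise ValueError(
                f"partition {p.method!r} covers a different id set; symmetric difference: {diff}"
            )
    missing = sorted(base - set(morphospecies))
    if missing:
        raise ValueError(f"ids lacking a morphospecies label: {missing}")
    by_species: dict[str, list[str]] = {}
    for sid in sorted(base):
        by_species.setdefault(morphospecies[sid], []).append(sid)
    rows = []
    for sp, ids in sorted(by_species.items()):
        row = ConsensusRow(species=sp, n_seqs=len(ids))
        for part in partitions:
            motus = {part.assignment[sid] for sid in ids}
            merged = any(
                morphospecies[other] != sp
                for other, motu in part.assignment.items()
                if motu in motus
            )
            row.per_method_motus[part.method] = len(motus)
            row.per_method_merged[part.method] = merged
        rows.append(row)
    return rows


def classify(
    rows: list[ConsensusRow],
    split_quorum: int = 4,
    single_quorum: int = 3,
    merge_quorum: int = 4,
) -> list[ConsensusRow]:
    """Fill row status (in place, also returned).

    Precedence: warning_split (>= split_quorum methods report >= 2 MOTUs),
    then warning_merge (>= merge_quorum methods report a shared MOTU), then
    congruent (>= single_quorum methods report exactly one unshared MOTU),
    else ambiguous.  Both warning flags are recorded even though only one
    becomes the status.
    """
    n_methods = len(rows[0].per_method_motus) if rows else 0
    if n_methods < max(split_quorum, single_quorum, merge_quorum):
        raise ValueError(
            f"{n_methods} methods present but quorums require "
            f"{max(split_quorum, single_quorum, merge_quorum)}"
        )
    for row in rows:
        n_split = sum(1 for v in row.per_method_motus.values() if v >= 2)
        n_merged = sum(1 for v in row.per_method_merged.values() if v)
        n_single = sum(
            1
            for m, v in row.per_method_motus.items()
            if v == 1 and not row.per_method_merged[m]
        )
        row.split_flag = n_split >= split_quorum
        row.merge_flag = n_merged >= merge_quorum
        if row.split_flag:
            row.status = "warning_split"
        elif row.merge_flag:
            row.status = "warning_merge"
        elif n_single >= single_quorum:
            row.status = "congruent"
        else:
            row.status = "ambiguous"
    return rows


def summarize(rows: list[ConsensusRow], partitions: list[Partition]) -> ConsensusReport:
    """Totals, match rate and composition over classified rows."""
    if any(r.status is None for r in rows):
        raise ValueError("rows must be classified first")
    n_congruent = sum(1 for r in rows if r.status == "congruent")
    n_warn = sum(1 for r in rows if r.status in ("warning_split", "warning_merge"))
    n_amb = sum(1 for r in rows if r.status == "ambiguous")
    n = len(rows)
    return ConsensusReport(
        rows=rows,
        n_congruent=n_congruent,
        n_warnings=n_warn,
        n_ambiguous=n_amb,
        match_rate=(n_congruent / n) if n else 0.0,
        method_motu_totals={p.method: p.n_motus() for p in partitions},
        composition={
            "n_singleton": sum(1 for r in rows if r.n_seqs == 1),
            "n_two": sum(1 for r in rows if r.n_seqs == 2),
            "n_multi": sum(1 for r in rows if r.n_seqs > 2),
        },
    )


def write_consensus_tsv(path, rows: list[ConsensusRow], max_intra: Mapping[str, float] | None = None,
                        header_lines: list[str] | None = None) -> None:
    """Table-1-style report: species, n sequences, per-method MOTU counts, status."""
    methods = list(rows[0].per_method_motus) if rows else []
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        cols = ["species", "n_seqs", *methods, "max_intra_pct", "status"]
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            mi = ""
            if max_intra and r.species in max_intra and max_intra[r.species] is not None:
                v = max_intra[r.species]
                mi = fmt_pct(v, 2) if math.isfinite(v) else "SATURATED"
            fh.write(
                "\t".join(
                    [r.species, str(r.n_seqs)]
                    + [str(r.per_method_motus[m]) for m in methods]
                    + [mi, r.status or ""]
                )
                + "\n"
            )


def load_reference_warning_table() -> list[ConsensusRow]:
    """Bundled published worked example: per-method MOTU counts for the 28
    Molytinae weevil morphospecies flagged for possible cryptic diversity
    in a six-method COI barcode comparison (ABGD, ASAP, BIN, bPTP, jMOTU,
    PTP).  Merge flags are not part of the published table and default to
    False."""
    ref = resources.files("barcodelim.data").joinpath("molytinae_warning_table.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", comment="#")
    methods = ["abgd", "asap", "bin", "bptp", "jmotu", "ptp"]
    rows = []
    for _, r in df.iterrows():
        rows.append(
            ConsensusRow(
                species=r["species"],
                n_seqs=int(r["n_seqs"]),
                per_method_motus={m: int(r[m]) for m in methods},
                per_method_merged={m: False for m in methods},
            )
        )
    return rows
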
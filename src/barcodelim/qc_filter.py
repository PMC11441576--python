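"""Sequence-inclusion filters applied before any distance or delimitation step.

Rules, applied in fixed order per sequence: minimum ungapped length,
ambiguous-base screen, stop-codon translation check (a NUMT/pseudogene
guard), and per-species exact-duplicate removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.Data import CodonTable

from .io_formats import SequenceRecord

__all__ = ["QcConfig", "QcReport", "apply_qc", "find_stop_codons"]

# Accepted names for genetic-code tables (NCBI numbering).
_TABLE_ALIASES = {
    "invertebrate-mito": 5,
    "invertebrate_mitochondrial": 5,
    "vertebrate-mito": 2,
    "standard": 1,
}


def _resolve_table(table: int | str) -> CodonTable.CodonTable:
    if isinstance(table, str):
        table = _TABLE_ALIASES.get(table.lower(), table)
    try:
        return CodonTable.unambiguous_dna_by_id[int(table)]
    except (ValueError, KeyError) as exc:
        raise ValueError(f"unknown genetic-code table {table!r}") from exc


@dataclass
class QcConfig:
    """Inclusion-rule parameters.

    min_length counts non-gap bases; max_ambiguous caps non-ACGT characters
    in the ungapped sequence (0 = reject any degenerate or missing base).
    """

    min_length: int = 600
    max_ambiguous: int = 0
    drop_duplicates_within_species: bool = True
    translation_check: bool = True
    translation_table: int | str = "invertebrate-mito"

    def __post_init__(self) -> None:
        if self.min_length <= 0:
            raise ValueError("min_length must be positive")
        if self.max_ambiguous < 0:
            raise ValueError("max_ambiguous must be >= 0")


@dataclass
class QcReport:
    n_input: int
    n_retained: int
    exclusions: list[tuple[str, str]] = field(default_factory=list)  # (seq_id, reason)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.exclusions, columns=["seq_id", "reason"])

    def write_tsv(self, path, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            fh.write(f"# n_input={self.n_input}\tn_retained={self.n_retained}\n")
            fh.write("seq_id\treason\n")
            for sid, reason in self.exclusions:
                fh.write(f"{sid}\t{reason}\n")


def find_stop_codons(sequence: str, table: int | str = "invertebrate-mito") -> tuple[int, int]:
    """Translate an ungapped DNA string in the three forward frames.

    Returns (best_frame, stop_count_in_best_frame) where the best frame has
    the fewest in-frame stop codons (ties broken by the lowest frame index).
    Codons containing any non-ACGT character are skipped, not counted.
    A protein-coding barcode in the correct reading frame must have zero
    stops; one or more in the best frame fails QC.
    """
    seq = sequence.replace("-", "").replace("?", "").upper()
    if len(seq) < 3:
        raise ValueError(f"sequence too short to translate ({len(seq)} bases)")
    stops = _resolve_table(table).stop_codons
    counts = []
    for frame in range(3):
        n = 0
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if set(codon) - set("ACGT"):
                continue
            if codon in stops:
                n += 1
        counts.append(n)
    best = min(range(3), key=lambda f: (counts[f], f))
    return best, counts[best]


def apply_qc(
    records: list[SequenceRecord], config: QcConfig | None = None
) -> tuple[list[SequenceRecord], QcReport]:
    """Filter records; never errors, each excluded id carries its first failing rule.

    Rule order: short -> ambiguous -> stop_codon -> duplicate.  Duplicates
    are identical ungapped sequence strings within the same morphospecies,
    keeping the first by input order.
    """
    config = config or QcConfig()
    retained: list[SequenceRecord] = []
    exclusions: list[tuple[str, str]] = []
    seen_by_species: dict[tuple[str, str], str] = {}
    for rec in records:
        ungapped = rec.ungapped
        if len(ungapped) < config.min_length:
            exclusions.append((rec.seq_id, "short"))
            continue
        n_ambig = sum(1 for c in ungapped if c not in "ACGT")
        if n_ambig > config.max_ambiguous:
            exclusions.append((rec.seq_id, "ambiguous"))
            continue
        if config.translation_check:
            _, n_stops = find_stop_codons(ungapped, config.translation_table)
            if n_stops > 0:
                exclusions.append((rec.seq_id, "stop_codon"))
                continue
        if config.drop_duplicates_within_species:
            key = (rec.species, ungapped)
            if key in seen_by_species:
                exclusions.append((rec.seq_id, "duplicate"))
                continue
            seen_by_species[key] = rec.seq_id
        retained.append(rec)
    report = QcReport(n_input=len(records), n_retained=len(retained), exclusions=exclusions)
    return retained, report
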
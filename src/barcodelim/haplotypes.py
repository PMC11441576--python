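"""Collapse aligned sequences into unique haplotypes with multiplicities."""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import AlignedMatrix

__all__ = ["Haplotype", "HaplotypeTable", "collapse_haplotypes"]

# IUPAC base sets; '-' and '?' are wildcard under the compatibility rule.
_IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"}, "-": {"A", "C", "G", "T"}, "?": {"A", "C", "G", "T"},
}
_WILD = frozenset("N-?")


@dataclass
class Haplotype:
    hap_id: str
    sequence: str  # representative = first member by input order
    members: list[str]
    species: set[str]
    localities: set[str]

    @property
    def count(self) -> int:
        return len(self.members)


@dataclass
class HaplotypeTable:
    haplotypes: list[Haplotype]

    def __len__(self) -> int:
        return len(self.haplotypes)

    @property
    def n_sequences(self) -> int:
        return sum(h.count for h in self.haplotypes)

    def member_ids(self) -> set[str]:
        return {m for h in self.haplotypes for m in h.members}

    def write_tsv(self, path, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            fh.write("hap_id\tcount\tmembers\tspecies\tlocalities\n")
            for h in self.haplotypes:
                fh.write(
                    f"{h.hap_id}\t{h.count}\t{','.join(h.members)}\t"
                    f"{','.join(sorted(h.species))}\t{','.join(sorted(x for x in h.localities if x))}\n"
                )

    def write_fasta(self, path) -> None:
        from .io_formats import write_fasta

        write_fasta(path, [(h.hap_id, h.sequence) for h in self.haplotypes])


def _compatible(a: str, b: str) -> bool:
    """Sequences of equal length are compatible if every site's IUPAC sets overlap."""
    for ca, cb in zip(a, b):
        if ca == cb:
            continue
        if ca in _WILD or cb in _WILD:
            continue
        if _IUPAC_SETS[ca].isdisjoint(_IUPAC_SETS[cb]):
            return False
    return True


def collapse_haplotypes(
    alignment: AlignedMatrix, treat_ambiguous_as_distinct: bool = True
) -> HaplotypeTable:
    """Condense an alignment into unique haplotypes.

    Default mode uses exact aligned-string equality.  With
    ``treat_ambiguous_as_distinct=False`` a sequence joins the first
    existing haplotype (by input order) whose representative it is
    IUPAC-compatible with ('N', '-', '?' match anything; partial code
    overlap suffices) — a greedy merge, order dependent by construction.
    Representative = first member; hap ids H0001... in appearance order.
    """
    haps: list[Haplotype] = []
    exact: dict[str, int] = {}
    for rec in alignment.records:
        target = None
        if treat_ambiguous_as_distinct:
            target = exact.get(rec.sequence)
        else:
            for i, h in enumerate(haps):
                if _compatible(rec.sequence, h.sequence):
                    target = i
                    break
        if target is None:
            haps.append(
                Haplotype(
                    hap_id=f"H{len(haps) + 1:04d}",
                    sequence=rec.sequence,
                    members=[rec.seq_id],
                    species={rec.species} if rec.species else set(),
                    localities={rec.locality} if rec.locality else set(),
                )
            )
            if treat_ambiguous_as_distinct:
                exact[rec.sequence] = len(haps) - 1
        else:
            h = haps[target]
            h.members.append(rec.seq_id)
            if rec.species:
                h.species.add(rec.species)
            if rec.locality:
                h.localities.add(rec.locality)
    return HaplotypeTable(haps)
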
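"""End-to-end orchestration: qc -> distances -> haplotypes -> delimitation -> consensus.

A run is driven by a RunConfig (deserializable from JSON), writes every
artifact as TSV/JSON into an output directory, stamps each file with the
config hash and seed, and is byte-reproducible for a fixed config+seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

from . import consensus as cons
from . import delimit_distance as dd
from . import delimit_tree as dt
from .distances import (
    distance_matrix,
    evaluate_threshold,
    fmt_pct,
    species_summaries,
    summarize_levels,
)
from .haplotypes import collapse_haplotypes
from .io_formats import (
    AlignedMatrix,
    Partition,
    read_fasta,
    read_metadata,
    read_newick,
    read_partition_tsv,
    write_partition_tsv,
)
from .qc_filter import QcConfig, apply_qc

log = logging.getLogger("barcodelim")

_STOCHASTIC = {"asap", "bptp", "ptp"}


@dataclass
class MethodSpec:
    name: str  # threshold | sweep | abgd | asap | ptp | bptp | external
    params: dict = field(default_factory=dict)


@dataclass
class RunConfig:
    fasta: str
    meta: str
    out_dir: str
    tree: str | None = None
    external_partitions: list[str] = field(default_factory=list)
    qc: QcConfig = field(default_factory=QcConfig)
    min_valid_sites: int = 300
    threshold_t: float = 0.03
    methods: list[MethodSpec] = field(
        default_factory=lambda: [
            MethodSpec("threshold", {"cutoff": 0.03}),
            MethodSpec("sweep", {"pick_bases": 20}),
            MethodSpec("abgd", {}),
            MethodSpec("asap", {}),
        ]
    )
    split_quorum: int = 4
    single_quorum: int = 3
    merge_quorum: int = 4
    seed: int | None = None

    def __post_init__(self) -> None:
        n_methods = len(self.methods) + len(self.external_partitions)
        if n_methods < 2:
            raise ValueError("consensus needs at least 2 delimitation methods")
        need = max(self.split_quorum, self.single_quorum, self.merge_quorum)
        if n_methods < need:
            raise ValueError(
                f"{n_methods} delimitation methods configured but the quorums "
                f"require at least {need}; add methods or lower the quorums"
            )
        if self.seed is None and any(m.name in _STOCHASTIC for m in self.methods):
            raise ValueError("a seed is required when stochastic methods are enabled")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        if "qc" in raw:
            raw["qc"] = QcConfig(**raw["qc"])
        if "methods" in raw:
            raw["methods"] = [MethodSpec(**m) for m in raw["methods"]]
        return cls(**raw)

    def canonical(self) -> dict:
        d = {
            "fasta": self.fasta,
            "meta": self.meta,
            "out_dir": self.out_dir,
            "tree": self.tree,
            "external_partitions": list(self.external_partitions),
            "qc": vars(self.qc),
            "min_valid_sites": self.min_valid_sites,
            "threshold_t": self.threshold_t,
            "methods": [{"name": m.name, "params": m.params} for m in self.methods],
            "split_quorum": self.split_quorum,
            "single_quorum": self.single_quorum,
            "merge_quorum": self.merge_quorum,
            "seed": self.seed,
        }
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _run_method(
    spec: MethodSpec,
    matrix,
    alignment: AlignedMatrix,
    tree_path: str | None,
    seed: int | None,
) -> list[Partition]:
    name = spec.name
    if name == "threshold":
        return [single := dd.single_linkage_threshold(matrix, spec.params.get("cutoff", 0.03))]
    if name == "sweep":
        sweep = dd.motu_sweep(
            matrix,
            alignment.alignment_length,
            cutoffs=spec.params.get("cutoffs"),
            ungapped_lengths={r.seq_id: len(r.ungapped) for r in alignment.records},
        )
        pick = spec.params.get("pick_bases", sweep.cutoffs_bases[-1])
        part = sweep.partitions[sweep.cutoffs_bases.index(pick)]
        return [part]
    if name == "abgd":
        cfg = dd.AbgdConfig(**spec.params) if spec.params else dd.AbgdConfig()
        parts = dd.abgd_partition(matrix, cfg)
        return [dd.abgd_stable_partition(parts)]  # modal plateau across the prior ladder
    if name == "asap":
        _, best = dd.asap_partition(matrix, seed=seed or 0)
        return [best]
    if name in ("ptp", "bptp"):
        if tree_path is None:
            raise ValueError(f"method {name!r} requires a rooted input tree")
        tree = read_newick(tree_path)
        it = dt.IndexedTree(tree)
        missing = set(it.leaf_label.values()) - set(matrix.ids)
        if missing:
            raise ValueError(f"tree leaves not in dataset: {sorted(missing)}")
        if name == "ptp":
            part, _ = dt.ptp_ml_search(it, seed=seed or 0)
            return [part]
        cfg = dt.McmcConfig(seed=seed or 0, **spec.params)
        _, _, part = dt.ptp_mcmc(it, cfg)
        return [part]
    raise ValueError(f"unknown delimitation method {name!r}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the summary dict (also written as JSON)."""
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = [f"config_hash={config.config_hash()}", f"seed={config.seed}"]

    log.info("[qc] reading %s", config.fasta)
    pairs = read_fasta(config.fasta)
    meta = read_metadata(config.meta)
    alignment = AlignedMatrix.from_sequences(pairs, meta)
    retained, report = apply_qc(list(alignment.records), config.qc)
    report.write_tsv(out / "qc_report.tsv", stamp)
    if len(retained) < 3:
        raise RuntimeError("stage qc: fewer than 3 sequences retained")
    alignment = AlignedMatrix(retained)
    log.info("[qc] retained %d / %d sequences", report.n_retained, report.n_input)

    log.info("[distances] %d x %d K2P matrix", len(alignment), len(alignment))
    matrix = distance_matrix(alignment, config.min_valid_sites)
    matrix.write_tsv(out / "matrix.tsv", stamp)
    taxa = alignment.taxon_map()
    levels = summarize_levels(matrix, taxa)
    summaries = species_summaries(matrix, taxa)
    thr_eval = evaluate_threshold(summaries, config.threshold_t)
    with open(out / "species_summaries.tsv", "w") as fh:
        for line in stamp:
            fh.write(f"# {line}\n")
        fh.write(
            "species\tn_seqs\tmax_intra\tmean_intra\tnearest_neighbor\tmin_inter_nn\tbarcode_gap\n"
        )
        for s in summaries:
            fh.write(
                "\t".join(
                    [
                        s.species,
                        str(s.n_seqs),
                        "" if s.max_intra is None else f"{s.max_intra:.6g}",
                        "" if s.mean_intra is None else f"{s.mean_intra:.6g}",
                        s.nearest_neighbor or "",
                        "" if s.min_inter_nn is None else f"{s.min_inter_nn:.6g}",
                        "" if s.barcode_gap is None else f"{s.barcode_gap:.6g}",
                    ]
                )
                + "\n"
            )

    log.info("[haplotypes] collapsing")
    haps = collapse_haplotypes(alignment)
    haps.write_tsv(out / "haps.tsv", stamp)

    partitions: list[Partition] = []
    for spec in config.methods:
        log.info("[delimit] %s", spec.name)
        try:
            parts = _run_method(spec, matrix, alignment, config.tree, config.seed)
        except Exception as exc:
            raise RuntimeError(f"stage delimit:{spec.name}: {exc}") from exc
        partitions.extend(parts)
    for path in config.external_partitions:
        partitions.append(read_partition_tsv(path, matrix.ids))
    for part in partitions:
        write_partition_tsv(out / f"partition_{part.method.replace(':', '_')}.tsv", part)
        with open(out / f"partition_{part.method.replace(':', '_')}.params.json", "w") as fh:
            json.dump({"method": part.method, "params": part.params}, fh, indent=2, default=str)

    log.info("[consensus] %d methods", len(partitions))
    rows = cons.tabulate(partitions, {sid: t.species for sid, t in taxa.items()})
    cons.classify(rows, config.split_quorum, config.single_quorum, config.merge_quorum)
    rep = cons.summarize(rows, partitions)
    cons.write_consensus_tsv(
        out / "consensus.tsv", rows,
        {s.species: s.max_intra for s in summaries}, stamp,
    )

    summary = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_input": report.n_input,
        "n_retained": report.n_retained,
        "n_species": rep.n_species,
        "composition": rep.composition,
        "composition_pct": {
            k: fmt_pct(v / rep.n_species, 1) for k, v in rep.composition.items()
        },
        "n_haplotypes": len(haps),
        "level_means_pct": {
            lvl: (None if st["mean"] is None else fmt_pct(st["mean"], 2))
            for lvl, st in levels.items()
        },
        "threshold_eval": {
            "t": thr_eval.t,
            "n_species_defined": thr_eval.n_species_defined,
            "fraction_defined_pct": fmt_pct(thr_eval.fraction_defined, 1),
            "n_intra_below": thr_eval.n_intra_below,
            "n_inter_above": thr_eval.n_inter_above,
        },
        "method_motu_totals": rep.method_motu_totals,
        "n_congruent": rep.n_congruent,
        "n_warnings": rep.n_warnings,
        "n_ambiguous": rep.n_ambiguous,
        "match_rate_pct": rep.match_rate_pct(),
        "warnings": sorted(
            r.species for r in rows if r.status in ("warning_split", "warning_merge")
        ),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("[done] %s", out / "summary.json")
    return summary
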
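# barcodelim

Single-locus DNA-barcode species delimitation and cryptic-diversity
screening, built for COI barcode surveys of diverse, under-studied animal
groups (the motivating case is weevil subfamilies with hundreds of
morphospecies and heavily skewed sequence sampling).

Morphological identification and molecular clustering rarely agree
perfectly: some morphospecies hide deeply divergent lineages (possible
cryptic species), others collapse into a single genetic cluster (possible
misidentification or synonymy). `barcodelim` implements the full
comparison pipeline:

1. **QC filters** — minimum length (default 600 bp of real bases),
   ambiguous-base screen, stop-codon translation check (invertebrate
   mitochondrial code; a pseudogene/NUMT guard), and per-species duplicate
   removal.
2. **K2P distances** — pairwise Kimura 2-parameter distances with pairwise
   deletion of ambiguous sites,

   `d = -(1/2)·ln(1 − 2P − Q) − (1/4)·ln(1 − 2Q)`

   where `P` and `Q` are the transition and transversion proportions over
   the jointly unambiguous sites; plus intra/inter distance pools by
   species/genus/subfamily, nearest-neighbour statistics, barcode gaps, and
   fixed-threshold evaluation ("which fraction of species is accurately
   defined at t = 3%?").
3. **Haplotype condensation** — unique haplotypes with multiplicities and
   metadata rollups (strict or IUPAC-ambiguity-compatible matching).
4. **MOTU delimitation** — four in-package methods plus external imports:
   * fixed-threshold single-linkage clustering and a jMOTU-style sweep over
     base-unit cutoffs (1–50);
   * recursive barcode-gap partitioning (ABGD-style, prior ladder
     0.005–0.1, relative gap width X = 1.0);
   * ranked-score partition selection over single-linkage merge heights
     (ASAP-style: permutation-test group homogeneity + relative gap width,
     mean-rank score, lowest score wins);
   * PTP maximum-likelihood delimitation on a user-supplied rooted tree
     (two-class exponential branch-length model) and a Bayesian variant
     (MCMC over delimitations with per-node support);
   * external partitions (e.g. BIN exports) read from two-column TSV.
5. **Consensus** — per-morphospecies method-by-method MOTU counts, with
   quorum rules: congruent if ≥ 3 methods put the species alone in one
   MOTU; *taxonomic warning* if ≥ 4 methods split it (cryptic diversity) or
   ≥ 4 merge it with another species; match rate and composition summary.

A seeded synthetic-data generator produces barcode datasets with known
truth (skewed sampling with ~44% singletons, within-species divergence
near 2.9%, between-species near 22%, optional deep splits and merge
pairs), so every stage is testable end to end without downloading data.

## Worked example

Simulate 10 morphospecies (4 sequences each, intra 1%, inter 10%) where
one species hides a deep split, then run the full pipeline with four
delimitation methods:

```bash
barcodelim simulate --n-species 10 --seqs-per-species 4 \
    --deep-split-fraction 0.1 --intra 0.01 --inter 0.10 \
    --seed 7 --outdir sim/

cat > run.json <<'JSON'
{
  "fasta": "sim/aln.fa", "meta": "sim/meta.tsv", "out_dir": "out",
  "qc": {"min_length": 600, "translation_check": false},
  "methods": [
    {"name": "threshold", "params": {"cutoff": 0.03}},
    {"name": "sweep", "params": {"pick_bases": 20}},
    {"name": "abgd", "params": {}},
    {"name": "asap", "params": {}}
  ],
  "seed": 11
}
JSON
barcodelim run --config run.json
```

`out/summary.json` then contains (abridged):

```json
{
  "level_means_pct": {"within_species": "1.44", "within_genus": "10.71"},
  "method_motu_totals": {"abgd": 11, "asap": 11, "jmotu": 11, "threshold": 11},
  "match_rate_pct": "90.0",
  "n_congruent": 9, "n_warnings": 1,
  "threshold_eval": {"t": 0.03, "n_species_defined": 9, "fraction_defined_pct": "90.0"},
  "warnings": ["sp001"]
}
```

Read: realized within-species divergence averaged 1.44% and
between-species 10.71%; all four methods found 11 MOTUs for the 10
morphospecies; the deliberately split species `sp001` was flagged as a
taxonomic warning by all methods (11th MOTU), giving a 90.0% match rate —
exactly the planted structure. (Translation checking is off because
synthetic sequences carry no codon structure; on real barcodes leave it
on.)

Every stage is also available as its own subcommand (`qc`, `distances`,
`haplotypes`, `delimit threshold|sweep|abgd|asap|ptp|bptp`, `consensus`,
`simulate`), reading and writing plain FASTA/TSV/newick/JSON.

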
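# ampfp — amplicon functional prediction toolkit

`ampfp` predicts microbial community functions from 16S rRNA amplicon data.
It builds a quality-filtered, per-domain (bacteria / archaea) reference
database of trait-annotated genomes on phylogenetic trees, places amplicon
sequence variants (ASVs) into **both** domain trees, selects the domain with
the lowest Nearest Sequenced Taxon Index (NSTI), infers gene content at each
placement by hidden-state prediction, and combines ASV abundances with
predicted 16S copy numbers to produce a predicted metagenome. A benchmarking
layer constructs mock communities from genomes held out of the reference
database — so their true functional profile is known exactly — and scores
predictions per sample with Spearman rank correlation and Bray–Curtis
dissimilarity, alongside abundance-weighted NSTIs.

All inputs can be generated synthetically (seeded Yule trees, Poisson
gain/loss trait evolution, a single-rate substitution model for 16S-like
sequences, log-normal community abundances), so nothing needs downloading.

## Design notes

* **Reference QC filter**: genomes must be representative, present in their
  domain tree, carry a 16S sequence passing length/ambiguity checks, and have
  contamination ≤ 10% and completeness ≥ 90% (inclusive, configurable). The
  16S criteria (`min_ssu_length`, `max_ssu_ambiguous_frac`) are explicit
  stand-ins recorded in the database manifest.
* **Placement** is a desk-scale substitute for alignment-based maximum
  likelihood placement: Jukes–Cantor-corrected pairwise distance to every
  reference 16S, nearest-tip grafting, pendant = corrected distance.
  Saturated distances (p ≥ 0.75) make a query unplaceable in that domain,
  which is the normal case for the "wrong" domain. The interface is abstract
  enough that an ML placement backend could be swapped in.
* **Hidden-state prediction**: Sankoff minimum-change parsimony (linear
  |a−b| cost over the observed integer state range, smallest co-optimal
  state on ties) for integer gene-family counts, inverse-distance weighting
  for 16S copy number and continuous traits. Exact sequence matches always
  return the matched genome's values verbatim.
* **Metagenome assembly**: `value(sample, function) = Σᵢ counts(i, sample) /
  copies(i) × traits(i, function)` with raw counts as weights; per-sample
  weighted NSTI is the abundance-weighted mean of per-ASV NSTIs. Default
  NSTI inclusion cutoff: 2.0 substitutions/site.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalences, perfect-recovery limit, domain-selection accuracy,
degradation monotonicity, filter boundary contract, metric oracles, and
byte-level chain determinism).

## CLI

```bash
# generate a complete synthetic world (database inputs, queries, mocks)
ampfp synth --seed 1 --out world/

# build the reference database from raw inputs
ampfp build-db --tree-bac world/tree_bacteria.nwk --tree-arc world/tree_archaea.nwk \
    --metadata world/metadata.tsv --ssu world/ssu.fna \
    --traits KO=world/traits_KO.tsv.gz --traits 16S=world/traits_16S.tsv.gz \
    --min-ssu-length 100 --out DB/

# dual-tree placement, NSTI, domain selection, 16S copy prediction
ampfp place --db DB/ --seqs world/mock/rep_seqs.fna --out placements.tsv

# hidden-state prediction for placed queries
ampfp hsp --db DB/ --placements placements.tsv --framework KO --method mp \
    --out predicted_traits.tsv.gz

# full pipeline: feature table (TSV or BIOM) -> predicted metagenome
ampfp predict --db DB/ --seqs world/mock/rep_seqs.fna --table world/mock/table.biom \
    --frameworks KO --out outdir/ --max-nsti 2.0

# score against mock-community gold standards
ampfp benchmark --db DB/ --mock-dir world/mock --frameworks KO --out report/
```

Outputs follow fixed conventions: `placements.tsv`,
`<FW>/pred_metagenome_unstrat.tsv.gz` (functions × samples),
`weighted_nsti.tsv`, and per-sample/summary TSVs plus `report.json` for
benchmarks. Column meanings are documented in the machine-readable schema
shipped at `src/ampfp/schema.json`. Every output directory receives a
`config.json` echo of the run configuration; gzipped outputs are written
with pinned headers so identical runs are byte-identical.

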
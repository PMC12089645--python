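{
  "placements.tsv": {
    "query_id": "query (ASV) identifier; index column",
    "nsti_bacteria": "NSTI in the bacterial tree, substitutions/site; empty when unplaceable/saturated",
    "nsti_archaea": "NSTI in the archaeal tree, substitutions/site; empty when unplaceable/saturated",
    "chosen_domain": "domain with the lowest NSTI ('bacteria', 'archaea', or 'unplaceable')",
    "chosen_nsti": "minimum of the defined per-domain NSTIs",
    "predicted_16S_copies": "distance-weighted 16S copy-number prediction, >= 1",
    "nearest_tip": "reference tip the query is attached to",
    "pendant_length": "branch length from the attachment point to the query",
    "distal_position": "attachment offset along the edge from its child node"
  },
  "weighted_nsti.tsv": {
    "sample": "sample identifier; index column",
    "weighted_nsti": "abundance-weighted mean NSTI over retained ASVs",
    "retained_asvs": "ASVs with nonzero count that survived placement and the NSTI cutoff",
    "excluded_asvs": "ASVs with nonzero count that were excluded"
  },
  "pred_metagenome_unstrat.tsv.gz": {
    "function": "function identifier; index column; lexicographic order",
    "<sample columns>": "predicted abundance: sum over ASVs of count/16S-copies * trait copy number"
  },
  "per_sample_<framework>.tsv": {
    "sample": "sample identifier; index column",
    "spearman_rho": "Spearman rank correlation (average ranks for ties) vs gold standard, union of function ids with absent = 0",
    "bray_curtis": "sum|p-g| / sum(p+g) over the union of function ids",
    "weighted_nsti": "abundance-weighted mean NSTI for the sample"
  },
  "hsp output": {
    "query_id": "query identifier; index column",
    "<trait columns>": "predicted copy number per trait",
    "NSTI": "chosen-domain NSTI passthrough"
  }
}
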
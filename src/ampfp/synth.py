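"""Seeded generators for every input the engine and benchmark need.

Pure-birth (Yule) trees with depth-scaled exponential branch lengths,
gain/loss random walks for integer trait copy numbers, a single-rate
substitution model for 16S-like sequences, log-normal community
abundances, and a one-call benchmark world that holds out a fraction of
tips as the mock-community pool. Everything is deterministic under the
config seed (independent child RNG streams are spawned per component).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import pandas as pd
from skbio import TreeNode

from ampfp.refdb import (
    ARCHAEA,
    BACTERIA,
    SSU_FRAMEWORK,
    GenomeRecord,
    QualityThresholds,
    ReferenceDatabase,
    TraitTable,
    build_reference,
    filter_report,
)
from ampfp.benchmark import MockCommunity
from ampfp.metagenome import FeatureTable

_BASES = np.array(list("ACGT"))


@dataclass
class TraitModel:
    n_traits: int = 16
    root_copy_min: int = 0
    root_copy_max: int = 4
    gain_rate: float = 1.0   # expected gains per unit branch length per trait
    loss_rate: float = 1.0
    ssu_root_copies: int = 4
    framework_id: str = "KO"


@dataclass
class SequenceModel:
    length: int = 600
    substitution_rate: float = 1.0  # substitutions/site per unit branch length


@dataclass
class CommunityModel:
    n_samples: int = 10
    lognormal_mean: float = 2.0
    lognormal_sigma: float = 1.0


@dataclass
class SynthConfig:
    seed: int = 0
    n_tips_bacteria: int = 40
    n_tips_archaea: int = 12
    birth_rate: float = 1.0
    tree_depth: float = 0.25  # target mean root-to-tip depth, subs/site
    trait_model: TraitModel = field(default_factory=TraitModel)
    sequence_model: SequenceModel = field(default_factory=SequenceModel)
    community_model: CommunityModel = field(default_factory=CommunityModel)
    heldout_fraction: float = 0.25

    def to_dict(self) -> dict:
        return asdict(self)


def _rng_streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_tree(
    n_tips: int,
    birth_rate: float = 1.0,
    tree_depth: float = 0.25,
    rng: np.random.Generator | None = None,
    prefix: str = "T",
) -> TreeNode:
    """Pure-birth tree with exponential waiting times, scaled to a target
    mean root-to-tip depth. Tips are named ``{prefix}{0001..}``."""
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    rng = rng if rng is not None else np.random.default_rng(0)

    root = TreeNode(name=None)
    active: list[TreeNode] = []
    birth_time: dict[int, float] = {}
    t = 0.0
    for _ in range(2):
        child = TreeNode(name=None)
        root.append(child)
        active.append(child)
        birth_time[id(child)] = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        idx = int(rng.integers(len(active)))
        node = active.pop(idx)
        node.length = t - birth_time.pop(id(node))
        for _ in range(2):
            child = TreeNode(name=None)
            node.append(child)
            active.append(child)
            birth_time[id(child)] = t
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    for node in active:
        node.length = t - birth_time.pop(id(node))

    # guard against zero-length branches (possible only via float underflow)
    for node in root.traverse(include_self=False):
        if node.length is not None and node.length <= 0:
            node.length = 1e-9

    depths = [sum(a.length for a in tip.ancestors() if a.length) + tip.length for tip in root.tips()]
    scale = tree_depth / float(np.mean(depths))
    for node in root.traverse(include_self=False):
        node.length *= scale

    for i, tip in enumerate(root.tips()):
        tip.name = f"{prefix}{i + 1:04d}"
    return root


def evolve_traits(
    tree: TreeNode, model: TraitModel, rng: np.random.Generator
) -> dict[str, pd.DataFrame]:
    """Evolve integer copy numbers down the tree by a Poisson gain/loss walk.

    Returns ``{framework_id: tips x traits, "16S": tips x 1}``; gene-family
    counts are floored at 0 and the 16S copy number at 1.
    """
    n = model.n_traits
    root_states = rng.integers(model.root_copy_min, model.root_copy_max + 1, size=n)
    root_full = np.concatenate([root_states, [model.ssu_root_copies]])

    states: dict[int, np.ndarray] = {id(tree): root_full.astype(np.int64)}
    tip_rows: dict[str, np.ndarray] = {}
    for node in tree.preorder(include_self=False):
        parent_state = states[id(node.parent)]
        length = node.length or 0.0
        gains = rng.poisson(model.gain_rate * length, size=n + 1)
        losses = rng.poisson(model.loss_rate * length, size=n + 1)
        state = parent_state + gains - losses
        state[:n] = np.maximum(state[:n], 0)
        state[n] = max(state[n], 1)
        states[id(node)] = state
        if node.is_tip():
            tip_rows[node.name] = state
    tips = sorted(tip_rows)
    matrix = np.vstack([tip_rows[t] for t in tips])
    trait_ids = [f"{model.framework_id}{i + 1:05d}" for i in range(n)]
    genes = pd.DataFrame(matrix[:, :n], index=tips, columns=trait_ids, dtype=float)
    ssu = pd.DataFrame(matrix[:, n:], index=tips, columns=["16S_rRNA_count"], dtype=float)
    return {model.framework_id: genes, SSU_FRAMEWORK: ssu}


def evolve_sequences(
    tree: TreeNode, model: SequenceModel, rng: np.random.Generator
) -> dict[str, str]:
    """Evolve sequences down the tree: Poisson substitution counts per branch,
    uniform positions, uniform alternative base."""
    if model.length < 100:
        raise ValueError("sequence length must be >= 100")
    root_seq = rng.integers(0, 4, size=model.length).astype(np.int8)
    seqs: dict[int, np.ndarray] = {id(tree): root_seq}
    out: dict[str, str] = {}
    for node in tree.preorder(include_self=False):
        seq = seqs[id(node.parent)].copy()
        length = node.length or 0.0
        n_sub = rng.poisson(model.substitution_rate * length * model.length)
        for _ in range(n_sub):
            pos = int(rng.integers(model.length))
            seq[pos] = (seq[pos] + 1 + rng.integers(3)) % 4
        seqs[id(node)] = seq
        if node.is_tip():
            out[node.name] = "".join(_BASES[seq])
    return out


def simulate_feature_table(
    asv_ids: list[str], model: CommunityModel, rng: np.random.Generator
) -> FeatureTable:
    """Log-normal abundances per (ASV, sample), rounded to integers >= 1."""
    ids = sorted(asv_ids)
    counts = rng.lognormal(
        model.lognormal_mean, model.lognormal_sigma, size=(len(ids), model.n_samples)
    )
    counts = np.maximum(np.rint(counts), 1.0)
    samples = [f"S{j + 1:03d}" for j in range(model.n_samples)]
    return FeatureTable(pd.DataFrame(counts, index=ids, columns=samples))


def synth_metadata(
    tip_ids: list[str], domain: str, rng: np.random.Generator
) -> pd.DataFrame:
    """Genome metadata for synthetic tips; all pass the default QC filter."""
    n = len(tip_ids)
    return pd.DataFrame(
        {
            "genome_id": tip_ids,
            "domain": domain,
            "completeness": np.round(rng.uniform(92.0, 100.0, size=n), 2),
            "contamination": np.round(rng.uniform(0.0, 8.0, size=n), 2),
            "is_representative": True,
            "in_domain_tree": True,
        }
    )


def synth_taxonomy(tip_ids: list[str], domain: str) -> pd.Series:
    """Placeholder per-genome taxonomy strings (unique species per genome)."""
    dom = "Bacteria" if domain == BACTERIA else "Archaea"
    return pd.Series(
        {
            gid: f"d__{dom};p__P1;c__C1;o__O1;f__F1;g__G_{gid};s__S_{gid}"
            for gid in tip_ids
        }
    )


@dataclass
class BenchmarkWorld:
    """A complete synthetic benchmark scenario."""

    config: SynthConfig
    database: ReferenceDatabase
    mock: MockCommunity
    feature_table: FeatureTable
    query_seqs: dict[str, str]
    trees: dict[str, TreeNode]            # full (pre-holdout) trees
    true_traits: dict[str, dict[str, pd.DataFrame]]   # domain -> framework -> tips x traits
    sequences: dict[str, dict[str, str]]  # domain -> tip -> sequence
    metadata: pd.DataFrame
    heldout: dict[str, list[str]]         # domain -> held-out tip ids


def diverge_heldout(
    world: "BenchmarkWorld", extra_depth: float, seed: int
) -> tuple[dict[str, str], pd.DataFrame, FeatureTable]:
    """Push the held-out genomes further from the reference.

    Each held-out genome's 16S sequence and trait annotations are evolved
    along one extra branch of length ``extra_depth`` under the world's
    sequence and trait models, and the gold standard is rebuilt from the
    evolved annotations. Returns (query sequences, gold standard, feature
    table); abundances are unchanged. ``extra_depth == 0`` reproduces the
    original world's queries and gold exactly.
    """
    from ampfp.benchmark import build_gold_standard

    cfg = world.config
    fw = cfg.trait_model.framework_id
    seq_rng, trait_rng = _rng_streams(seed, 2)
    sm, tm = cfg.sequence_model, cfg.trait_model

    query_seqs: dict[str, str] = {}
    gene_rows: dict[str, pd.Series] = {}
    ssu_rows: dict[str, float] = {}
    base_to_int = {b: i for i, b in enumerate("ACGT")}
    for domain in sorted(world.heldout):
        gene = world.true_traits[domain][fw]
        ssu = world.true_traits[domain][SSU_FRAMEWORK]
        for gid in world.heldout[domain]:
            seq = np.array([base_to_int[c] for c in world.sequences[domain][gid]], dtype=np.int8)
            n_sub = seq_rng.poisson(sm.substitution_rate * extra_depth * len(seq))
            for _ in range(n_sub):
                pos = int(seq_rng.integers(len(seq)))
                seq[pos] = (seq[pos] + 1 + seq_rng.integers(3)) % 4
            query_seqs[gid] = "".join(_BASES[seq])

            g = gene.loc[gid].to_numpy(dtype=np.int64)
            gains = trait_rng.poisson(tm.gain_rate * extra_depth, size=len(g))
            losses = trait_rng.poisson(tm.loss_rate * extra_depth, size=len(g))
            gene_rows[gid] = pd.Series(np.maximum(g + gains - losses, 0), index=gene.columns)
            s = int(ssu.loc[gid].iloc[0])
            s += int(trait_rng.poisson(tm.gain_rate * extra_depth)) - int(
                trait_rng.poisson(tm.loss_rate * extra_depth)
            )
            ssu_rows[gid] = float(max(s, 1))

    annotations = pd.DataFrame(gene_rows).T.astype(float)
    copies = pd.Series(ssu_rows)
    table = world.feature_table
    gold = build_gold_standard(table.data, annotations, copies)
    return query_seqs, gold, table


def make_benchmark_world(
    config: SynthConfig,
    query_mode: Literal["heldout", "tips"] = "heldout",
) -> BenchmarkWorld:
    """Simulate trees, traits, and sequences per domain; hold out a seeded
    fraction of tips as the mock pool; build the reference database from
    the remainder.

    With ``query_mode="tips"`` the queries are the *retained* tips
    themselves (exact reference matches), the perfect-recovery limit used
    by the test-suite.
    """
    if not (0.0 < config.heldout_fraction <= 0.5):
        raise ValueError("heldout_fraction must be in (0, 0.5]")
    streams = _rng_streams(config.seed, 10)
    (tree_b_rng, tree_a_rng, trait_b_rng, trait_a_rng, seq_b_rng, seq_a_rng,
     hold_rng, comm_rng, meta_rng, _spare) = streams

    spec = {
        BACTERIA: (config.n_tips_bacteria, "B", tree_b_rng, trait_b_rng, seq_b_rng),
        ARCHAEA: (config.n_tips_archaea, "A", tree_a_rng, trait_a_rng, seq_a_rng),
    }
    trees: dict[str, TreeNode] = {}
    traits: dict[str, dict[str, pd.DataFrame]] = {}
    seqs: dict[str, dict[str, str]] = {}
    heldout: dict[str, list[str]] = {}
    retained: dict[str, list[str]] = {}
    for domain, (n_tips, prefix, t_rng, tr_rng, s_rng) in spec.items():
        tree = simulate_tree(n_tips, config.birth_rate, config.tree_depth, t_rng, prefix)
        trees[domain] = tree
        traits[domain] = evolve_traits(tree, config.trait_model, tr_rng)
        seqs[domain] = evolve_sequences(tree, config.sequence_model, s_rng)
        tips = sorted(t.name for t in tree.tips())
        n_hold = max(1, int(round(config.heldout_fraction * len(tips))))
        held = sorted(hold_rng.choice(tips, size=n_hold, replace=False).tolist())
        heldout[domain] = held
        retained[domain] = [t for t in tips if t not in held]

    # reference database from retained tips only
    fw = config.trait_model.framework_id
    all_gene = pd.concat([traits[d][fw] for d in spec], axis=0).fillna(0.0)
    all_ssu = pd.concat([traits[d][SSU_FRAMEWORK] for d in spec], axis=0)
    all_seqs = {t: s for d in spec for t, s in seqs[d].items()}
    trait_tables = {
        fw: TraitTable(fw, all_gene),
        SSU_FRAMEWORK: TraitTable(SSU_FRAMEWORK, all_ssu),
    }
    metadata_frames = []
    for domain in spec:
        md = synth_metadata(retained[domain], domain, meta_rng)
        metadata_frames.append(md)
    metadata = pd.concat(metadata_frames, ignore_index=True)

    records = []
    for _, row in metadata.iterrows():
        gid = row["genome_id"]
        records.append(
            GenomeRecord(
                genome_id=gid,
                domain=row["domain"],
                completeness=float(row["completeness"]),
                contamination=float(row["contamination"]),
                is_representative=True,
                in_domain_tree=True,
                ssu_sequence=all_seqs[gid],
            )
        )
    thresholds = QualityThresholds(min_ssu_length=100)
    survivors, counts = filter_report(records, thresholds)
    database = build_reference(
        trees, trait_tables, all_seqs, survivors, thresholds, stage_counts=counts
    )

    # mock community from held-out genomes
    held_all = sorted(heldout[BACTERIA] + heldout[ARCHAEA])
    if query_mode == "heldout":
        query_ids = held_all
    elif query_mode == "tips":
        query_ids = sorted(retained[BACTERIA] + retained[ARCHAEA])
    else:
        raise ValueError(f"unknown query_mode {query_mode!r}")
    query_seqs = {q: all_seqs[q] for q in query_ids}
    feature_table = simulate_feature_table(query_ids, config.community_model, comm_rng)

    mock_genomes = query_ids
    gold_inputs_ann = all_gene.loc[mock_genomes]
    gold_inputs_ssu = all_ssu.loc[mock_genomes, all_ssu.columns[0]]
    from ampfp.benchmark import build_gold_standard  # local import avoids cycle at module load

    gold = build_gold_standard(feature_table.data, gold_inputs_ann, gold_inputs_ssu)
    mock = MockCommunity(
        genome_ids=list(mock_genomes),
        abundances=feature_table.data,
        representative_sequences=query_seqs,
        gold_standard={fw: gold},
        template_dataset_label="synthetic",
    )
    if query_mode == "heldout":
        ref_tips = {t for ref in database.domains.values() for t in ref.tip_ids}
        mock.assert_heldout(ref_tips)

    return BenchmarkWorld(
        config=config,
        database=database,
        mock=mock,
        feature_table=feature_table,
        query_seqs=query_seqs,
        trees=trees,
        true_traits=traits,
        sequences=seqs,
        metadata=metadata,
        heldout=heldout,
    )
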
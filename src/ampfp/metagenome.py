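"""Predicted-metagenome assembly from feature tables and predicted traits.

Counts are divided by predicted 16S copy number, then multiplied through
the query x trait matrix: value(sample, function) =
sum_i counts(i, sample) / copies(i) * traits(i, function). Raw counts are
used as weights (no rarefaction or relative-abundance conversion); the
per-sample weighted NSTI is the abundance-weighted mean of per-ASV NSTIs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ampfp import hsp as hsp_module
from ampfp.placement import (
    DEFAULT_MAX_NSTI,
    QUERY_TIP_LABEL,
    PlacementSet,
    graft_query,
    place_queries,
)
from ampfp.refdb import SSU_FRAMEWORK, ReferenceDatabase

logger = logging.getLogger(__name__)


class FeatureTable:
    """ASV x sample matrix of non-negative counts."""

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate ASV ids in feature table: {dups}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids in feature table: {dups}")
        values = data.astype(float)
        neg = values.lt(0).any(axis=1)
        if neg.any():
            raise ValueError(
                f"negative counts in feature table rows: {values.index[neg].tolist()}"
            )
        empty = values.columns[values.sum(axis=0) == 0].tolist()
        if empty:
            warnings.warn(f"samples with zero total count: {empty}", stacklevel=2)
        self.data = values

    @property
    def asv_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, FeatureTable) and self.data.equals(other.data)

    def __repr__(self) -> str:
        r, c = self.data.shape
        return f"FeatureTable({r} ASVs x {c} samples)"


@dataclass
class MetagenomeMatrix:
    """Sample x function predicted abundances with per-sample diagnostics."""

    data: pd.DataFrame  # samples x functions
    weighted_nsti: pd.Series  # per sample
    retained_asvs: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))
    excluded_asvs: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))
    stratified: pd.DataFrame | None = None  # (asv, function) x samples when requested


def _align_copies(table: FeatureTable, copies: pd.Series) -> pd.Series:
    missing = [a for a in table.asv_ids if a not in copies.index]
    if missing:
        raise KeyError(f"missing 16S copy number for ASVs: {missing}")
    aligned = copies.loc[table.asv_ids].astype(float)
    if (aligned < 1).any():
        bad = aligned.index[aligned < 1].tolist()
        raise ValueError(f"16S copy numbers below 1 for ASVs: {bad}")
    return aligned


def normalize_by_copy_number(table: FeatureTable, copies: pd.Series) -> FeatureTable:
    """Divide each ASV's counts by its predicted 16S copy number."""
    aligned = _align_copies(table, copies)
    return FeatureTable(table.data.div(aligned, axis=0))


def predict_metagenome(
    normalized: FeatureTable,
    traits: pd.DataFrame,
    nsti: pd.Series | None = None,
    stratified: bool = False,
) -> MetagenomeMatrix:
    """Accumulate copy-number-normalized abundances through the trait matrix.

    ``traits`` is indexed by ASV id (must cover every ASV in the table);
    ``nsti`` (per ASV) feeds the per-sample weighted NSTI. Functions are
    emitted in lexicographic order, samples in input order.
    """
    missing = [a for a in normalized.asv_ids if a not in traits.index]
    if missing:
        raise KeyError(f"traits missing for ASVs: {missing}")
    t = traits.loc[normalized.asv_ids].astype(float)
    t = t[sorted(t.columns)]
    values = normalized.data.T.to_numpy() @ t.to_numpy()
    data = pd.DataFrame(values, index=normalized.sample_ids, columns=t.columns)
    if nsti is not None:
        wn = weighted_nsti(normalized, nsti)
    else:
        wn = pd.Series(np.nan, index=normalized.sample_ids)
    strat = None
    if stratified:
        blocks = {
            asv: t.loc[asv].to_numpy()[:, None] * normalized.data.loc[asv].to_numpy()[None, :]
            for asv in normalized.asv_ids
        }
        strat = pd.concat(
            {
                asv: pd.DataFrame(block, index=t.columns, columns=normalized.sample_ids)
                for asv, block in blocks.items()
            },
            names=["asv", "function"],
        )
    return MetagenomeMatrix(data=data, weighted_nsti=wn, stratified=strat)


def weighted_nsti(table: FeatureTable, nsti: pd.Series) -> pd.Series:
    """Per-sample abundance-weighted mean NSTI; NaN for empty samples."""
    missing = [a for a in table.asv_ids if a not in nsti.index]
    if missing:
        raise KeyError(f"NSTI missing for ASVs: {missing}")
    n = nsti.loc[table.asv_ids].astype(float)
    totals = table.data.sum(axis=0)
    out = table.data.mul(n, axis=0).sum(axis=0) / totals.replace(0.0, np.nan)
    empty = totals.index[totals == 0].tolist()
    if empty:
        warnings.warn(f"weighted NSTI undefined for zero-count samples: {empty}", stacklevel=2)
    return out


def apply_nsti_cutoff(
    table: FeatureTable, nsti: pd.Series, max_nsti: float = DEFAULT_MAX_NSTI
) -> tuple[FeatureTable, pd.DataFrame]:
    """Drop ASVs with NSTI above the cutoff; report what was removed.

    Samples losing all their ASVs are retained as all-zero columns with a
    warning rather than dropped.
    """
    if max_nsti <= 0:
        raise ValueError(f"max_nsti must be positive, got {max_nsti}")
    n = _align_series(nsti, table.asv_ids, "NSTI")
    excluded_mask = n > max_nsti
    report = pd.DataFrame(
        {"nsti": n[excluded_mask]},
    )
    report.index.name = "asv_id"
    keep = [a for a in table.asv_ids if not excluded_mask[a]]
    kept_data = table.data.loc[keep]
    zeroed = kept_data.columns[kept_data.sum(axis=0) == 0].tolist()
    if zeroed:
        logger.warning("samples left with no ASVs after NSTI cutoff: %s", zeroed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        filtered = FeatureTable(kept_data)
    return filtered, report


def _align_series(series: pd.Series, ids: list[str], what: str) -> pd.Series:
    missing = [a for a in ids if a not in series.index]
    if missing:
        raise KeyError(f"{what} missing for ASVs: {missing}")
    return series.loc[ids].astype(float)


@dataclass
class PredictionResult:
    """Everything the ``predict`` pipeline produces."""

    placements: PlacementSet
    metagenomes: dict[str, MetagenomeMatrix]  # per framework
    predicted_traits: dict[str, pd.DataFrame]  # per framework, queries x traits
    exclusion_report: pd.DataFrame


def predict_query_trait_matrix(
    db: ReferenceDatabase,
    placement_set: PlacementSet,
    framework: str,
    method: str = "max_parsimony",
) -> pd.DataFrame:
    """Hidden-state predictions for all retained queries in one framework."""
    rows = {}
    for qid, placement in placement_set.placements.items():
        ref = db.domains[placement.domain]
        if framework not in ref.trait_tables:
            raise KeyError(f"framework {framework!r} not in {placement.domain} database")
        table = ref.trait_tables[framework]
        grafted = graft_query(ref.tree, placement)
        rows[qid] = hsp_module.predict_query_traits(
            grafted, table.data, QUERY_TIP_LABEL, method=method
        )
    if not rows:
        return pd.DataFrame()
    return pd.DataFrame(rows).T.fillna(0.0).sort_index()


def run_prediction(
    db: ReferenceDatabase,
    query_seqs: dict[str, str],
    table: FeatureTable,
    frameworks: list[str] | None = None,
    method: str = "max_parsimony",
    max_nsti: float = DEFAULT_MAX_NSTI,
    stratified: bool = False,
) -> PredictionResult:
    """Full engine: place, select domain, HSP, normalize, accumulate.

    ASVs present in the table but absent from the query sequences are an
    error; queries without table rows are ignored for the metagenome but
    still placed (their NSTI appears in the placement records).
    """
    frameworks = frameworks or [fw for fw in db.frameworks if fw != SSU_FRAMEWORK]
    missing_seqs = [a for a in table.asv_ids if a not in query_seqs]
    if missing_seqs:
        raise KeyError(f"feature-table ASVs without sequences: {missing_seqs}")

    placement_set = place_queries(db, query_seqs, max_nsti=max_nsti)
    records = placement_set.records

    retained = [a for a in table.asv_ids if a in placement_set.placements]
    dropped = [a for a in table.asv_ids if a not in placement_set.placements]
    exclusion = records.loc[dropped, ["chosen_nsti", "chosen_domain"]].copy() if dropped else (
        pd.DataFrame(columns=["chosen_nsti", "chosen_domain"])
    )
    if dropped:
        logger.info("%d ASV(s) excluded (unplaceable or NSTI > %.3g)", len(dropped), max_nsti)
    if not retained:
        raise ValueError("no ASV survived placement and the NSTI cutoff")

    sub = FeatureTable(table.data.loc[retained])
    copies = records.loc[retained, "predicted_16S_copies"]
    nsti = records.loc[retained, "chosen_nsti"]
    normalized = normalize_by_copy_number(sub, copies)

    # per-sample retained/excluded ASV counts (ASVs with nonzero count)
    present = table.data > 0
    retained_counts = present.loc[retained].sum(axis=0).astype(int)
    excluded_counts = (
        present.loc[dropped].sum(axis=0).astype(int)
        if dropped
        else pd.Series(0, index=table.sample_ids)
    )

    metagenomes: dict[str, MetagenomeMatrix] = {}
    predicted: dict[str, pd.DataFrame] = {}
    for fw in frameworks:
        fw_method = "distance_weighted" if fw == SSU_FRAMEWORK else method
        traits = predict_query_trait_matrix(db, placement_set, fw, method=fw_method)
        predicted[fw] = traits
        mm = predict_metagenome(normalized, traits.loc[retained], nsti=None, stratified=stratified)
        # weight NSTI by raw (pre-normalization) counts
        mm.weighted_nsti = weighted_nsti(sub, nsti)
        mm.retained_asvs = retained_counts
        mm.excluded_asvs = excluded_counts
        metagenomes[fw] = mm
    return PredictionResult(
        placements=placement_set,
        metagenomes=metagenomes,
        predicted_traits=predicted,
        exclusion_report=exclusion,
    )
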
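"""Mock-community benchmarking: gold standards, Spearman, Bray-Curtis.

Mock communities are assembled from genomes deliberately held out of the
reference database, so their true functional profile (the gold standard) is
computable exactly: gold(sample, function) =
sum_g abundance(g, sample) / ssu_copies(g) * annotation(g, function) — the
same weighting contract as the prediction engine, applied with true values.
Predictions are scored per sample with Spearman rank correlation (average
ranks for ties) and Bray-Curtis dissimilarity over the union of function
ids (absent = 0).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
_RANK_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")


@dataclass
class MockCommunity:
    """Held-out genomes with per-sample abundances and true functional profiles."""

    genome_ids: list[str]
    abundances: pd.DataFrame  # genomes x samples
    representative_sequences: dict[str, str]
    gold_standard: dict[str, pd.DataFrame] = field(default_factory=dict)  # framework -> samples x functions
    template_dataset_label: str = ""

    def assert_heldout(self, reference_tip_ids: set[str]) -> None:
        overlap = sorted(set(self.genome_ids) & reference_tip_ids)
        if overlap:
            raise ValueError(f"mock genomes present in the reference database: {overlap}")


def parse_taxonomy(taxonomy: str) -> dict[str, str]:
    """Parse 'd__X;p__Y;...' into rank -> name (missing/blank ranks omitted)."""
    out: dict[str, str] = {}
    for token in taxonomy.split(";"):
        token = token.strip()
        for rank, prefix in zip(RANKS, _RANK_PREFIXES):
            if token.startswith(prefix):
                name = token[len(prefix):].strip()
                if name:
                    out[rank] = name
    return out


def match_taxa_to_heldout(
    community_profile: pd.DataFrame,
    pool_taxonomy: pd.Series,
    min_retained_fraction: float = 0.5,
    strict: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Map each community taxon to a held-out pool genome.

    ``community_profile`` is taxon x sample abundances, indexed by taxonomy
    strings; ``pool_taxonomy`` maps genome_id -> taxonomy string. Each taxon
    is matched to the pool genome sharing the deepest taxonomic rank
    (species before genus before ...); equally deep matches resolve to the
    lexicographically smaller genome_id. Unmatched taxa are dropped. Returns
    (genome x sample abundances, report dict).
    """
    pool = {gid: parse_taxonomy(t) for gid, t in pool_taxonomy.items()}
    assignments: dict[str, str] = {}
    for taxon in community_profile.index:
        want = parse_taxonomy(str(taxon))
        for rank in reversed(RANKS):  # deepest first
            if rank not in want:
                continue
            hits = sorted(
                gid for gid, tax in pool.items() if tax.get(rank) == want[rank]
            )
            if hits:
                assignments[taxon] = hits[0]
                break

    total = float(community_profile.to_numpy().sum())
    matched_rows = community_profile.loc[list(assignments)] if assignments else (
        community_profile.iloc[0:0]
    )
    retained = float(matched_rows.to_numpy().sum())
    fraction = retained / total if total > 0 else 0.0
    report = {
        "n_taxa": int(community_profile.shape[0]),
        "n_matched": len(assignments),
        "retained_abundance_fraction": fraction,
        "assignments": dict(assignments),
    }
    if fraction < min_retained_fraction:
        msg = (
            f"only {fraction:.1%} of community abundance matched to held-out genomes "
            f"(threshold {min_retained_fraction:.0%})"
        )
        if strict:
            raise ValueError(msg)
        logger.warning(msg)
    if not assignments:
        return pd.DataFrame(columns=community_profile.columns), report
    # taxa mapping to the same genome pool their abundances
    abundances = matched_rows.groupby(
        pd.Index([assignments[t] for t in matched_rows.index], name="genome_id")
    ).sum()
    return abundances, report


def build_gold_standard(
    abundances: pd.DataFrame,
    annotations: pd.DataFrame,
    ssu_copies: pd.Series,
    normalize_by_copies: bool = True,
) -> pd.DataFrame:
    """True sample x function profile of a mock community.

    ``abundances``: genomes x samples; ``annotations``: genomes x functions;
    ``ssu_copies``: true 16S copy number per genome. With
    ``normalize_by_copies`` off, raw abundances weight the annotations.
    """
    genomes = list(abundances.index)
    missing = [g for g in genomes if g not in annotations.index]
    if missing:
        raise KeyError(f"annotations missing for mock genomes: {missing}")
    missing = [g for g in genomes if g not in ssu_copies.index]
    if missing:
        raise KeyError(f"16S copy numbers missing for mock genomes: {missing}")
    weights = abundances.astype(float)
    if normalize_by_copies:
        weights = weights.div(ssu_copies.loc[genomes].astype(float), axis=0)
    ann = annotations.loc[genomes].astype(float)
    ann = ann[sorted(ann.columns)]
    gold = pd.DataFrame(
        weights.T.to_numpy() @ ann.to_numpy(), index=abundances.columns, columns=ann.columns
    )
    return gold


def _union_vectors(pred: pd.Series, gold: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    ids = sorted(set(pred.index) | set(gold.index))
    p = pred.reindex(ids, fill_value=0.0).to_numpy(dtype=float)
    g = gold.reindex(ids, fill_value=0.0).to_numpy(dtype=float)
    return p, g


def spearman_per_sample(pred: pd.Series, gold: pd.Series) -> float:
    """Spearman rank correlation over the union of function ids (absent = 0)."""
    p, g = _union_vectors(pred, gold)
    if np.ptp(p) == 0 or np.ptp(g) == 0:
        warnings.warn("Spearman undefined for a zero-variance vector", stacklevel=2)
        return float("nan")
    rho, _ = stats.spearmanr(p, g)
    return float(rho)


def bray_curtis_per_sample(pred: pd.Series, gold: pd.Series) -> float:
    """Bray-Curtis dissimilarity sum|p-g| / sum(p+g) over the union of ids."""
    p, g = _union_vectors(pred, gold)
    if (p < 0).any() or (g < 0).any():
        raise ValueError("Bray-Curtis requires non-negative vectors")
    denom = (p + g).sum()
    if denom == 0:
        warnings.warn("Bray-Curtis undefined for two all-zero vectors", stacklevel=2)
        return float("nan")
    return float(np.abs(p - g).sum() / denom)


@dataclass
class EvaluationResult:
    """Per-sample scores for one database/framework combination."""

    per_sample: pd.DataFrame  # index sample; spearman_rho, bray_curtis, weighted_nsti
    label: str = ""
    dataset: str = ""

    def medians(self) -> pd.Series:
        return self.per_sample.median()

    def ranges(self) -> pd.DataFrame:
        return pd.DataFrame({"min": self.per_sample.min(), "max": self.per_sample.max()})


def evaluate_predictions(
    predicted: pd.DataFrame,
    gold: pd.DataFrame,
    weighted_nsti: pd.Series | None = None,
    label: str = "",
    dataset: str = "",
) -> EvaluationResult:
    """Score sample x function predictions against the gold standard."""
    missing = [s for s in gold.index if s not in predicted.index]
    if missing:
        raise ValueError(f"samples missing from predictions: {missing}")
    rows = {}
    for sample in gold.index:
        rows[sample] = {
            "spearman_rho": spearman_per_sample(predicted.loc[sample], gold.loc[sample]),
            "bray_curtis": bray_curtis_per_sample(predicted.loc[sample], gold.loc[sample]),
            "weighted_nsti": float(weighted_nsti[sample])
            if weighted_nsti is not None
            else float("nan"),
        }
    per_sample = pd.DataFrame.from_dict(rows, orient="index")
    per_sample.index.name = "sample"
    return EvaluationResult(per_sample=per_sample, label=label, dataset=dataset)


def compare_databases(
    eval_a: EvaluationResult,
    eval_b: EvaluationResult,
    alpha: float = 0.05,
) -> dict:
    """Paired per-metric comparison of two evaluations on the same samples.

    Reports medians, ranges, a two-sided paired t-test p-value and a
    significance flag at P <= alpha per metric. Identical paired values
    yield p = 1 (no flag).
    """
    a, b = eval_a.per_sample, eval_b.per_sample
    if set(a.index) != set(b.index):
        only_a = sorted(set(a.index) - set(b.index))
        only_b = sorted(set(b.index) - set(a.index))
        raise ValueError(f"sample mismatch: only in a={only_a}, only in b={only_b}")
    b = b.loc[a.index]
    report: dict = {"label_a": eval_a.label, "label_b": eval_b.label, "n_samples": len(a), "metrics": {}}
    for metric in ("spearman_rho", "bray_curtis", "weighted_nsti"):
        xa, xb = a[metric].to_numpy(dtype=float), b[metric].to_numpy(dtype=float)
        ok = ~(np.isnan(xa) | np.isnan(xb))
        xa, xb = xa[ok], xb[ok]
        diffs = xa - xb
        if len(diffs) == 0:
            p_value = float("nan")
        elif np.allclose(diffs, 0.0):
            p_value = 1.0
        elif np.ptp(diffs) == 0:
            # constant nonzero shift: t statistic degenerates to +/- inf
            p_value = 0.0
        else:
            p_value = float(stats.ttest_rel(xa, xb).pvalue)
        report["metrics"][metric] = {
            "median_a": float(np.median(xa)) if len(xa) else float("nan"),
            "median_b": float(np.median(xb)) if len(xb) else float("nan"),
            "range_a": [float(xa.min()), float(xa.max())] if len(xa) else [float("nan")] * 2,
            "range_b": [float(xb.min()), float(xb.max())] if len(xb) else [float("nan")] * 2,
            "median_difference": float(np.median(diffs)) if len(diffs) else float("nan"),
            "p_value": p_value,
            "significant": bool(p_value <= alpha) if not np.isnan(p_value) else False,
        }
    return report
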
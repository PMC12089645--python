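"""Phylogenetic placement of query ASVs and NSTI computation.

This is a desk-scale placement: each query is compared against every
reference 16S sequence, a Jukes-Cantor-corrected distance is computed, and
the query is grafted onto the terminal edge of the nearest tip, at the tip,
with the corrected distance as pendant length. The interface is kept
abstract enough that a maximum-likelihood placement backend could be
swapped in.

NSTI (nearest sequenced taxon index) is the minimum over reference tips of
pendant length plus the path length from the attachment point to that tip;
with nearest-tip attachment this reduces to the pendant length. Queries are
placed in both domain trees and the domain with the lowest NSTI wins
(ties -> bacteria).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from ampfp import hsp
from ampfp.refdb import BACTERIA, ARCHAEA, SSU_FRAMEWORK, DomainReference, ReferenceDatabase

logger = logging.getLogger(__name__)

#: p-distances at or above this are treated as saturated (JC undefined).
SATURATION_P = 0.75
#: minimum number of comparable (both-unambiguous) positions for a distance.
MIN_INFORMATIVE_POSITIONS = 50
#: default NSTI cutoff for downstream inclusion (substitutions/site).
DEFAULT_MAX_NSTI = 2.0

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lower case


def encode_sequence(seq: str) -> np.ndarray:
    """Encode ACGT as 0..3 and anything else (ambiguity codes) as 255."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def p_distance(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    """Proportion of mismatches over positions where both are unambiguous.

    Unequal-length sequences are compared at the best ungapped offset
    (maximum identity over the overlap). Returns (p, n_informative).
    """
    if len(a) == len(b):
        return _p_distance_aligned(a, b)
    short, long_ = (a, b) if len(a) < len(b) else (b, a)
    best = (1.0, 0)
    best_matches = -1
    for offset in range(len(long_) - len(short) + 1):
        window = long_[offset : offset + len(short)]
        p, n = _p_distance_aligned(short, window)
        matches = int(round((1 - p) * n))
        if matches > best_matches:
            best_matches = matches
            best = (p, n)
    return best


def _p_distance_aligned(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    informative = (a != 255) & (b != 255)
    n = int(informative.sum())
    if n == 0:
        return 1.0, 0
    mismatches = int((a[informative] != b[informative]).sum())
    return mismatches / n, n


def jukes_cantor(p: float) -> float:
    """JC69 distance for proportion ``p``; NaN when saturated (p >= 0.75)."""
    if p >= SATURATION_P:
        return float("nan")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


@dataclass
class Placement:
    """Attachment of one query onto one domain tree.

    ``attachment_edge`` is (parent node name or None, child node name); the
    desk-scale placer always attaches on the terminal edge of the nearest
    tip, at the tip end (``distal_position == 0``).
    """

    query_id: str
    domain: str
    attachment_edge: tuple[str | None, str]
    distal_position: float
    pendant_length: float

    @property
    def child_node(self) -> str:
        return self.attachment_edge[1]

    def __post_init__(self) -> None:
        if self.pendant_length < 0:
            raise ValueError(f"{self.query_id}: pendant_length must be >= 0")
        if self.distal_position < 0:
            raise ValueError(f"{self.query_id}: distal_position must be >= 0")


@dataclass
class NstiRecord:
    query_id: str
    nsti_bacteria: float | None
    nsti_archaea: float | None
    chosen_domain: str | None
    chosen_nsti: float | None

    @property
    def placeable(self) -> bool:
        return self.chosen_domain is not None


class DomainPlacer:
    """Caches encoded reference sequences for repeated placements in one domain."""

    def __init__(self, ref: DomainReference):
        self.ref = ref
        self.tip_ids = sorted(ref.ssu_sequences)
        self._encoded = [encode_sequence(ref.ssu_sequences[t]) for t in self.tip_ids]
        lengths = {len(e) for e in self._encoded}
        self._matrix = (
            np.vstack(self._encoded) if len(lengths) == 1 else None
        )

    def distances(self, query_seq: str) -> pd.Series:
        """JC distance from the query to every reference tip (NaN = saturated
        or too few informative positions)."""
        q = encode_sequence(query_seq)
        out = np.full(len(self.tip_ids), np.nan)
        if self._matrix is not None and len(q) == self._matrix.shape[1]:
            informative = (self._matrix != 255) & (q[None, :] != 255)
            n = informative.sum(axis=1)
            mism = ((self._matrix != q[None, :]) & informative).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                p = np.where(n > 0, mism / np.maximum(n, 1), 1.0)
            ok = n >= MIN_INFORMATIVE_POSITIONS
            for i in np.flatnonzero(ok):
                out[i] = jukes_cantor(float(p[i]))
        else:
            for i, ref_enc in enumerate(self._encoded):
                p, n = p_distance(q, ref_enc)
                if n >= MIN_INFORMATIVE_POSITIONS:
                    out[i] = jukes_cantor(p)
        return pd.Series(out, index=self.tip_ids)

    def place(self, query_id: str, query_seq: str) -> Placement | None:
        d = self.distances(query_seq)
        defined = d.dropna()
        if defined.empty:
            return None
        best = defined.min()
        # lexicographically smallest id among equidistant nearest tips
        nearest = sorted(defined.index[defined == best])[0]
        tip = self.ref.tree.find(nearest)
        parent_name = tip.parent.name if tip.parent is not None else None
        return Placement(
            query_id=query_id,
            domain=self.ref.domain,
            attachment_edge=(parent_name, nearest),
            distal_position=0.0,
            pendant_length=float(best),
        )


def place_query(query_id: str, query_seq: str, ref: DomainReference) -> Placement | None:
    """One-shot placement of a single query into one domain tree."""
    if len(query_seq) < 50:
        raise ValueError(f"{query_id}: query shorter than 50 nt")
    return DomainPlacer(ref).place(query_id, query_seq)


def compute_nsti(placement: Placement, tree: TreeNode) -> float:
    """Minimum over tips of pendant length + path from the attachment point.

    The attachment point sits ``distal_position`` above the child node of
    ``attachment_edge``; tips below the child are reached downward, all
    other tips upward through the parent.
    """
    child = tree.find(placement.child_node)
    x = placement.distal_position
    if child.parent is not None and child.length is not None and x > child.length + 1e-12:
        raise ValueError(
            f"{placement.query_id}: distal_position {x} exceeds edge length {child.length}"
        )
    below = {t.name for t in child.tips()} if not child.is_tip() else {child.name}
    dists = hsp.node_to_tip_distances(child)
    best = np.inf
    for tip, d in dists.items():
        cand = x + d if tip in below else d - x
        best = min(best, cand)
    return placement.pendant_length + float(best)


def select_domain(
    query_id: str, nsti_bacteria: float | None, nsti_archaea: float | None
) -> NstiRecord:
    """Choose the domain with the lowest NSTI; ties go to bacteria."""

    def _defined(v: float | None) -> bool:
        return v is not None and not np.isnan(v)

    bac_ok, arc_ok = _defined(nsti_bacteria), _defined(nsti_archaea)
    if not bac_ok and not arc_ok:
        return NstiRecord(query_id, None, None, None, None)
    if bac_ok and (not arc_ok or nsti_bacteria <= nsti_archaea):
        chosen, value = BACTERIA, nsti_bacteria
    else:
        chosen, value = ARCHAEA, nsti_archaea
    return NstiRecord(query_id, nsti_bacteria, nsti_archaea, chosen, float(value))


#: reserved tip label for grafted queries (avoids collisions when a query id
#: equals a reference tip id, e.g. in exact-recovery tests)
QUERY_TIP_LABEL = "__query__"


def graft_query(tree: TreeNode, placement: Placement) -> TreeNode:
    """Return a copy of ``tree`` with the query grafted per the placement.

    A new internal node is inserted on the attachment edge at
    ``distal_position`` above the child node, and the query hangs from it
    with the pendant length under the reserved label ``QUERY_TIP_LABEL``.
    ``distal_position == 0`` at a tip keeps the tip on a zero-length stub so
    reference tip identities are preserved.
    """
    tree = tree.copy()
    child = tree.find(placement.child_node)
    x = placement.distal_position
    parent = child.parent
    if parent is None:
        raise ValueError(f"cannot graft onto the root edge of {placement.child_node!r}")
    edge_len = child.length
    attach = TreeNode(name=None, length=edge_len - x)
    parent.remove(child)
    child.length = x
    attach.append(child)
    query_tip = TreeNode(name=QUERY_TIP_LABEL, length=placement.pendant_length)
    attach.append(query_tip)
    parent.append(attach)
    return tree


def predict_copy_number(placement: Placement, ref: DomainReference) -> float:
    """Distance-weighted 16S copy-number prediction at the attachment point, clamped to >= 1."""
    table = ref.trait_tables[SSU_FRAMEWORK]
    grafted = graft_query(ref.tree, placement)
    value = hsp.hsp_distance_weighted(grafted, table.data, QUERY_TIP_LABEL)
    return max(1.0, float(value.iloc[0]))


@dataclass
class PlacementSet:
    """Per-query placement results across both domains."""

    records: pd.DataFrame  # index query_id; nsti/domain/copy columns
    placements: dict[str, Placement]  # chosen-domain placement per placeable query


def place_queries(
    db: ReferenceDatabase,
    query_seqs: dict[str, str],
    max_nsti: float = DEFAULT_MAX_NSTI,
) -> PlacementSet:
    """Place every query in every domain tree, select domains, predict copies.

    Queries that are unplaceable in both domains or whose chosen NSTI
    exceeds ``max_nsti`` are excluded from ``placements`` (but appear in
    ``records``); exclusions are logged as summary counts only.
    """
    placers = {d: DomainPlacer(ref) for d, ref in db.domains.items()}
    rows = []
    chosen: dict[str, Placement] = {}
    n_unplaceable = 0
    n_over_cutoff = 0
    for qid in sorted(query_seqs):
        seq = query_seqs[qid]
        per_domain: dict[str, Placement | None] = {}
        nsti: dict[str, float | None] = {BACTERIA: None, ARCHAEA: None}
        for domain, placer in placers.items():
            pl = placer.place(qid, seq)
            per_domain[domain] = pl
            if pl is not None:
                nsti[domain] = compute_nsti(pl, placer.ref.tree)
        rec = select_domain(qid, nsti.get(BACTERIA), nsti.get(ARCHAEA))
        copies = np.nan
        if rec.placeable:
            pl = per_domain[rec.chosen_domain]
            copies = predict_copy_number(pl, db.domains[rec.chosen_domain])
            if rec.chosen_nsti <= max_nsti:
                chosen[qid] = pl
            else:
                n_over_cutoff += 1
        else:
            n_unplaceable += 1
        rows.append(
            {
                "query_id": qid,
                "nsti_bacteria": np.nan if rec.nsti_bacteria is None else rec.nsti_bacteria,
                "nsti_archaea": np.nan if rec.nsti_archaea is None else rec.nsti_archaea,
                "chosen_domain": rec.chosen_domain or "unplaceable",
                "chosen_nsti": np.nan if rec.chosen_nsti is None else rec.chosen_nsti,
                "predicted_16S_copies": copies,
                "nearest_tip": per_domain[rec.chosen_domain].child_node if rec.placeable else "",
                "pendant_length": per_domain[rec.chosen_domain].pendant_length
                if rec.placeable
                else np.nan,
                "distal_position": per_domain[rec.chosen_domain].distal_position
                if rec.placeable
                else np.nan,
            }
        )
    if n_unplaceable:
        logger.warning("%d quer(ies) unplaceable in every domain", n_unplaceable)
    if n_over_cutoff:
        logger.info("%d quer(ies) above the NSTI cutoff %.3g", n_over_cutoff, max_nsti)
    df = pd.DataFrame(rows).set_index("query_id")
    return PlacementSet(records=df, placements=chosen)
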
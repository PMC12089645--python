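"""Reference database construction: genome QC filtering, tree pruning, trait tables.

A reference database holds, per domain (bacteria / archaea), a phylogenetic
tree whose tips are genome ids, one trait table per annotation framework
(e.g. "KO", "EC") plus the distinguished single-column "16S" copy-number
table, and a 16S sequence per tip. Genomes enter the database only if they
are flagged representative, are present in their domain's tree, carry a
high-quality 16S sequence, and pass contamination/completeness thresholds
(inclusive inequalities: contamination <= max, completeness >= min).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

BACTERIA = "bacteria"
ARCHAEA = "archaea"
DOMAINS = (BACTERIA, ARCHAEA)

SSU_FRAMEWORK = "16S"

#: IUPAC nucleotide one-letter codes (upper case; input is upcased first).
IUPAC_NT = frozenset("ACGTURYSWKMBDHVN")
_UNAMBIGUOUS = frozenset("ACGT")

# Rejection reasons, checked in this order; the first failure is recorded.
REASON_NOT_REPRESENTATIVE = "not_representative"
REASON_NOT_IN_TREE = "not_in_tree"
REASON_SSU_FAIL = "ssu_fail"
REASON_CONTAMINATION = "contamination"
REASON_COMPLETENESS = "completeness"
FILTER_REASONS = (
    REASON_NOT_REPRESENTATIVE,
    REASON_NOT_IN_TREE,
    REASON_SSU_FAIL,
    REASON_CONTAMINATION,
    REASON_COMPLETENESS,
)


@dataclass(frozen=True)
class QualityThresholds:
    """Genome and 16S quality-control thresholds.

    The contamination/completeness defaults implement the published filter
    (<= 10% contamination, >= 90% completeness). The 16S criteria
    (``min_ssu_length``, ``max_ssu_ambiguous_frac``) are explicit,
    configurable stand-ins — the exact published 16S QC criteria are not
    restated here — and are recorded in the build manifest.
    """

    max_contamination: float = 10.0
    min_completeness: float = 90.0
    min_ssu_length: int = 1200
    max_ssu_ambiguous_frac: float = 0.01

    def __post_init__(self) -> None:
        if not (0 <= self.max_contamination <= 100):
            raise ValueError(f"max_contamination out of [0,100]: {self.max_contamination}")
        if not (0 <= self.min_completeness <= 100):
            raise ValueError(f"min_completeness out of [0,100]: {self.min_completeness}")
        if self.min_ssu_length < 0:
            raise ValueError(f"min_ssu_length negative: {self.min_ssu_length}")
        if not (0 <= self.max_ssu_ambiguous_frac <= 1):
            raise ValueError(
                f"max_ssu_ambiguous_frac out of [0,1]: {self.max_ssu_ambiguous_frac}"
            )


@dataclass
class GenomeRecord:
    genome_id: str
    domain: str
    completeness: float
    contamination: float
    is_representative: bool
    in_domain_tree: bool
    ssu_sequence: str | None = None

    def validate(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(
                f"genome {self.genome_id!r}: domain must be one of {DOMAINS}, got {self.domain!r}"
            )
        for name, value in (("completeness", self.completeness), ("contamination", self.contamination)):
            try:
                v = float(value)
            except (TypeError, ValueError):
                raise ValueError(f"genome {self.genome_id!r}: malformed {name} {value!r}") from None
            if not np.isfinite(v) or not (0.0 <= v <= 100.0):
                raise ValueError(
                    f"genome {self.genome_id!r}: {name} {value!r} outside [0, 100]"
                )


def validate_ssu(sequence: str | None, thresholds: QualityThresholds) -> bool:
    """Return True iff the 16S sequence passes quality control.

    A sequence passes when present, at least ``min_ssu_length`` nucleotides
    long, and with a fraction of ambiguous (non-ACGT IUPAC) characters at
    most ``max_ssu_ambiguous_frac``. Characters outside the IUPAC alphabet
    raise ``ValueError``.
    """
    if sequence is None or sequence == "":
        return False
    seq = sequence.upper()
    bad = set(seq) - IUPAC_NT
    if bad:
        raise ValueError(f"non-IUPAC characters in 16S sequence: {sorted(bad)!r}")
    if len(seq) < thresholds.min_ssu_length:
        return False
    n_ambiguous = sum(1 for c in seq if c not in _UNAMBIGUOUS)
    return n_ambiguous / len(seq) <= thresholds.max_ssu_ambiguous_frac


def classify_genome(record: GenomeRecord, thresholds: QualityThresholds) -> str | None:
    """Return the first rejection reason for a record, or None if it is kept."""
    record.validate()
    if not record.is_representative:
        return REASON_NOT_REPRESENTATIVE
    if not record.in_domain_tree:
        return REASON_NOT_IN_TREE
    if not validate_ssu(record.ssu_sequence, thresholds):
        return REASON_SSU_FAIL
    if record.contamination > thresholds.max_contamination:
        return REASON_CONTAMINATION
    if record.completeness < thresholds.min_completeness:
        return REASON_COMPLETENESS
    return None


def filter_genomes(
    records: Sequence[GenomeRecord],
    thresholds: QualityThresholds | None = None,
) -> list[GenomeRecord]:
    """Keep records passing every quality filter, preserving input order."""
    thresholds = thresholds or QualityThresholds()
    return [r for r in records if classify_genome(r, thresholds) is None]


def filter_report(
    records: Sequence[GenomeRecord],
    thresholds: QualityThresholds | None = None,
) -> tuple[list[GenomeRecord], dict[str, int]]:
    """As :func:`filter_genomes`, additionally returning per-reason rejection counts.

    Counts satisfy ``kept + sum(rejected per reason) == len(records)``.
    """
    thresholds = thresholds or QualityThresholds()
    kept: list[GenomeRecord] = []
    counts: dict[str, int] = {"input": len(records), "kept": 0}
    counts.update({r: 0 for r in FILTER_REASONS})
    for rec in records:
        reason = classify_genome(rec, thresholds)
        if reason is None:
            kept.append(rec)
            counts["kept"] += 1
        else:
            counts[reason] += 1
    return kept, counts


class TraitTable:
    """Genome/query x trait matrix of non-negative copy numbers.

    Zero and absent are semantically identical; the matrix is stored dense
    (float64) but constructors accept sparse-style dicts. The distinguished
    ``"16S"`` framework has exactly one trait column with every value >= 1.
    """

    def __init__(self, framework_id: str, data: pd.DataFrame):
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate row ids in {framework_id!r} trait table: {dups}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate trait ids in {framework_id!r} trait table: {dups}")
        values = data.astype(float)
        if (values.to_numpy() < 0).any():
            raise ValueError(f"negative values in {framework_id!r} trait table")
        if framework_id == SSU_FRAMEWORK:
            if values.shape[1] != 1:
                raise ValueError(
                    f"16S trait table must have exactly one column, got {values.shape[1]}"
                )
            if (values.to_numpy() < 1).any():
                raise ValueError("16S copy numbers must all be >= 1")
        self.framework_id = framework_id
        self.data = values

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def trait_ids(self) -> list[str]:
        return list(self.data.columns)

    def subset(self, row_ids: Iterable[str]) -> "TraitTable":
        row_ids = list(row_ids)
        missing = [r for r in row_ids if r not in self.data.index]
        if missing:
            raise KeyError(
                f"genomes missing from {self.framework_id!r} trait table: {missing}"
            )
        return TraitTable(self.framework_id, self.data.loc[row_ids])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, TraitTable)
            and self.framework_id == other.framework_id
            and self.data.equals(other.data)
        )

    def __repr__(self) -> str:
        r, c = self.data.shape
        return f"TraitTable({self.framework_id!r}, {r} rows x {c} traits)"


def _check_branch_lengths(tree: TreeNode) -> None:
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValueError(f"branch length missing on node {node.name!r}")
        if node.length < 0:
            raise ValueError(f"negative branch length {node.length} on node {node.name!r}")


@dataclass
class DomainReference:
    """One domain's slice of a reference database."""

    domain: str
    tree: TreeNode
    trait_tables: dict[str, TraitTable]
    ssu_sequences: dict[str, str]

    @property
    def tip_ids(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def validate(self) -> None:
        _check_branch_lengths(self.tree)
        tips = self.tip_ids
        tip_set = set(tips)
        if len(tips) != len(tip_set):
            raise ValueError(f"{self.domain}: duplicate tip labels in tree")
        if SSU_FRAMEWORK not in self.trait_tables:
            raise ValueError(f"{self.domain}: missing mandatory 16S trait table")
        for fw, table in self.trait_tables.items():
            rows = set(table.row_ids)
            missing = sorted(tip_set - rows)
            if missing:
                raise ValueError(
                    f"{self.domain}: tree tips missing from {fw!r} trait table: {missing}"
                )
            extra = sorted(rows - tip_set)
            if extra:
                raise ValueError(
                    f"{self.domain}: {fw!r} trait table rows not in tree: {extra}"
                )
        no_seq = sorted(tip_set - set(self.ssu_sequences))
        if no_seq:
            raise ValueError(f"{self.domain}: tree tips without a 16S sequence: {no_seq}")


@dataclass
class ReferenceDatabase:
    domains: dict[str, DomainReference]
    manifest: dict = field(default_factory=dict)

    def validate(self) -> None:
        for ref in self.domains.values():
            ref.validate()

    @property
    def frameworks(self) -> list[str]:
        fw: list[str] = []
        for ref in self.domains.values():
            for name in ref.trait_tables:
                if name not in fw:
                    fw.append(name)
        return fw


def prune_tree(tree: TreeNode, keep_tips: Sequence[str]) -> TreeNode:
    """Prune a tree to ``keep_tips``, merging lengths of collapsed unifurcations.

    Pairwise path lengths between surviving tips are preserved exactly.
    """
    tip_names = {t.name for t in tree.tips()}
    missing = sorted(set(keep_tips) - tip_names)
    if missing:
        raise KeyError(f"tips not present in tree: {missing}")
    pruned = tree.shear(list(keep_tips))
    pruned.prune()
    return pruned


def build_domain_reference(
    domain: str,
    tree: TreeNode,
    trait_tables: Mapping[str, TraitTable],
    ssu_sequences: Mapping[str, str],
    surviving_ids: Sequence[str],
) -> DomainReference:
    """Prune one domain tree to survivors and subset tables/sequences to match."""
    surviving_ids = list(surviving_ids)
    if not surviving_ids:
        raise ValueError(f"{domain}: no surviving genomes")
    pruned = prune_tree(tree, surviving_ids)
    tables: dict[str, TraitTable] = {}
    for fw, table in trait_tables.items():
        try:
            tables[fw] = table.subset(surviving_ids)
        except KeyError as exc:
            raise ValueError(
                f"{domain}: surviving genome absent from {fw!r} trait table: {exc}"
            ) from exc
    missing_seqs = [g for g in surviving_ids if g not in ssu_sequences]
    if missing_seqs:
        raise ValueError(f"{domain}: surviving genomes without a 16S sequence: {missing_seqs}")
    seqs = {g: ssu_sequences[g] for g in surviving_ids}
    ref = DomainReference(domain=domain, tree=pruned, trait_tables=tables, ssu_sequences=seqs)
    ref.validate()
    return ref


def build_reference(
    trees: Mapping[str, TreeNode],
    trait_tables: Mapping[str, TraitTable],
    ssu_sequences: Mapping[str, str],
    surviving: Sequence[GenomeRecord],
    thresholds: QualityThresholds | None = None,
    stage_counts: Mapping[str, int] | None = None,
    version: str = "ampfp-db-1",
) -> ReferenceDatabase:
    """Assemble the per-domain reference database from filter survivors.

    ``trees`` maps domain name to the (unpruned) domain tree; trait tables
    may carry rows for genomes of both domains and are subset per domain.
    The manifest records the thresholds, the per-stage filter counts, and
    the per-domain survivor counts.
    """
    thresholds = thresholds or QualityThresholds()
    by_domain: dict[str, list[str]] = {d: [] for d in trees}
    for rec in surviving:
        if rec.domain not in by_domain:
            raise ValueError(f"genome {rec.genome_id!r}: no tree provided for domain {rec.domain!r}")
        by_domain[rec.domain].append(rec.genome_id)

    domains: dict[str, DomainReference] = {}
    for domain, ids in by_domain.items():
        if not ids:
            continue
        domains[domain] = build_domain_reference(
            domain, trees[domain], trait_tables, ssu_sequences, ids
        )
    if not domains:
        raise ValueError("no domain has any surviving genome")

    manifest = {
        "version": version,
        "thresholds": asdict(thresholds),
        "ssu_qc_note": (
            "min_ssu_length and max_ssu_ambiguous_frac are configurable "
            "stand-in criteria for 16S quality control"
        ),
        "filter_counts": dict(stage_counts) if stage_counts else {},
        "genomes_per_domain": {d: len(r.tip_ids) for d, r in domains.items()},
        "frameworks": sorted({fw for r in domains.values() for fw in r.trait_tables}),
    }
    return ReferenceDatabase(domains=domains, manifest=manifest)


def add_user_framework(db: ReferenceDatabase, table: TraitTable) -> ReferenceDatabase:
    """Register a user-supplied trait table under a new framework id.

    The table must cover every tree tip of at least one domain; it is
    attached to every domain it fully covers. Existing frameworks are never
    overwritten.
    """
    if table.framework_id in db.frameworks:
        raise ValueError(f"framework {table.framework_id!r} already exists; refusing to overwrite")
    rows = set(table.row_ids)
    covered: dict[str, DomainReference] = {}
    gaps: dict[str, list[str]] = {}
    for domain, ref in db.domains.items():
        missing = sorted(set(ref.tip_ids) - rows)
        if missing:
            gaps[domain] = missing
        else:
            covered[domain] = ref
    if not covered:
        detail = "; ".join(f"{d}: missing {m}" for d, m in gaps.items())
        raise ValueError(
            f"framework {table.framework_id!r} covers no domain completely ({detail})"
        )
    new_domains: dict[str, DomainReference] = {}
    for domain, ref in db.domains.items():
        tables = dict(ref.trait_tables)
        if domain in covered:
            tables[table.framework_id] = table.subset(ref.tip_ids)
        new_domains[domain] = DomainReference(
            domain=domain, tree=ref.tree, trait_tables=tables, ssu_sequences=ref.ssu_sequences
        )
    manifest = dict(db.manifest)
    manifest["frameworks"] = sorted(
        {fw for r in new_domains.values() for fw in r.trait_tables}
    )
    out = ReferenceDatabase(domains=new_domains, manifest=manifest)
    out.validate()
    return out


def records_from_metadata(
    metadata: pd.DataFrame, ssu_sequences: Mapping[str, str] | None = None
) -> list[GenomeRecord]:
    """Build GenomeRecords from a metadata frame (columns: genome_id, domain,
    completeness, contamination, is_representative, in_domain_tree)."""
    required = {
        "genome_id",
        "domain",
        "completeness",
        "contamination",
        "is_representative",
        "in_domain_tree",
    }
    missing = required - set(metadata.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    ssu_sequences = ssu_sequences or {}
    records = []
    for _, row in metadata.iterrows():
        gid = str(row["genome_id"])
        records.append(
            GenomeRecord(
                genome_id=gid,
                domain=str(row["domain"]),
                completeness=float(row["completeness"]),
                contamination=float(row["contamination"]),
                is_representative=_as_bool(row["is_representative"]),
                in_domain_tree=_as_bool(row["in_domain_tree"]),
                ssu_sequence=ssu_sequences.get(gid),
            )
        )
    return records


def _as_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in {"true", "1", "yes", "t"}:
        return True
    if s in {"false", "0", "no", "f"}:
        return False
    raise ValueError(f"cannot interpret {value!r} as boolean")


def manifest_to_json(manifest: dict) -> str:
    return json.dumps(manifest, indent=2, sort_keys=True)
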
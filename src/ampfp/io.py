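"""Readers and writers for the standard formats used across the toolkit.

Newick trees (branch lengths required), FASTA, tab-separated trait and
feature tables (transparently gzipped by extension), BIOM 2.1 (HDF5)
feature tables, JSON/YAML configs, and the on-disk reference-database
layout::

    DB/
      manifest.json
      bacteria/tree.nwk  ssu.fna  traits_16S.tsv.gz  traits_KO.tsv.gz ...
      archaea/...
"""

from __future__ import annotations

import json
import gzip
from datetime import datetime
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

from ampfp.metagenome import FeatureTable
from ampfp.refdb import DomainReference, ReferenceDatabase, TraitTable, _check_branch_lengths

_HDF5_MAGIC = b"\x89HDF\r\n\x1a\n"

#: significant digits for numeric TSV output
FLOAT_FORMAT = "%.6g"


def _open_text_write(path: str | Path):
    """Text handle for writing; .gz paths get a reproducible gzip stream
    (mtime pinned to 0, no filename in the header) so identical content
    yields identical bytes."""
    if str(path).endswith(".gz"):
        raw = open(path, "wb")
        return gzip.GzipFile(fileobj=raw, mode="wb", mtime=0, filename="")

    return open(path, "w", encoding="utf-8")


def _write_text(path: str | Path, text: str) -> None:
    handle = _open_text_write(path)
    try:
        if isinstance(handle, gzip.GzipFile):
            handle.write(text.encode("utf-8"))
        else:
            handle.write(text)
    finally:
        fileobj = getattr(handle, "fileobj", None)
        handle.close()
        if fileobj is not None:
            fileobj.close()


# -- Newick -----------------------------------------------------------------

def read_newick(path: str | Path) -> TreeNode:
    tree = TreeNode.read(str(path), format="newick")
    _check_branch_lengths(tree)
    return tree


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


# -- FASTA ------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Parse FASTA into an id -> sequence dict (id = first header token)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    seqs: dict[str, str] = {}
    current: str | None = None
    chunks: list[str] = []
    with opener(path, "rt") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if current is not None:
                    seqs[current] = "".join(chunks)
                current = line[1:].split()[0]
                if current in seqs:
                    raise ValueError(f"duplicate sequence id {current!r} in {path}")
                chunks = []
            elif line:
                chunks.append(line.strip())
    if current is not None:
        seqs[current] = "".join(chunks)
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    lines: list[str] = []
    for name in seqs:
        lines.append(f">{name}")
        seq = seqs[name]
        lines.extend(seq[i : i + width] for i in range(0, len(seq), width))
    _write_text(path, "\n".join(lines) + "\n" if lines else "")


# -- TSV tables -------------------------------------------------------------

def read_tsv_matrix(path: str | Path, index_name: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, compression="infer")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if index_name:
        df.index.name = index_name
    return df


def write_tsv_matrix(df: pd.DataFrame, path: str | Path, index_label: str | None = None) -> None:
    text = df.to_csv(
        sep="\t",
        float_format=FLOAT_FORMAT,
        index_label=index_label or df.index.name or "id",
    )
    _write_text(path, text)


def read_trait_table(path: str | Path, framework_id: str) -> TraitTable:
    return TraitTable(framework_id, read_tsv_matrix(path, index_name="genome_id"))


def write_trait_table(table: TraitTable, path: str | Path) -> None:
    write_tsv_matrix(table.data, path, index_label="genome_id")


# -- Feature tables (TSV / BIOM 2.1) ---------------------------------------

def read_feature_table(path: str | Path) -> FeatureTable:
    """Auto-detect TSV vs BIOM-HDF5 and parse; ids preserved verbatim."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(8)
    if magic == _HDF5_MAGIC:
        import biom

        table = biom.load_table(str(path))
        df = table.to_dataframe(dense=True)  # observations x samples
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return FeatureTable(df)
    df = read_tsv_matrix(path, index_name="asv_id")
    return FeatureTable(df)


def write_feature_table_tsv(table: FeatureTable, path: str | Path) -> None:
    write_tsv_matrix(table.data, path, index_label="asv_id")


def write_feature_table_biom(table: FeatureTable, path: str | Path) -> None:
    import biom
    import h5py

    bt = biom.Table(
        table.data.to_numpy(),
        observation_ids=list(table.data.index),
        sample_ids=list(table.data.columns),
    )
    with h5py.File(str(path), "w") as fh:
        # pinned creation date so identical tables are byte-identical
        bt.to_hdf5(fh, generated_by="ampfp",
                   creation_date=datetime(1970, 1, 1, 0, 0, 0))


# -- JSON / YAML ------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def read_yaml(path: str | Path):
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_yaml(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


# -- Reference database layout ----------------------------------------------

def save_reference_database(db: ReferenceDatabase, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_json(db.manifest, out / "manifest.json")
    for domain, ref in db.domains.items():
        ddir = out / domain
        ddir.mkdir(exist_ok=True)
        write_newick(ref.tree, ddir / "tree.nwk")
        write_fasta(ref.ssu_sequences, ddir / "ssu.fna")
        for fw, table in ref.trait_tables.items():
            write_trait_table(table, ddir / f"traits_{fw}.tsv.gz")


def load_reference_database(db_dir: str | Path) -> ReferenceDatabase:
    root = Path(db_dir)
    manifest = read_json(root / "manifest.json") if (root / "manifest.json").exists() else {}
    domains: dict[str, DomainReference] = {}
    for ddir in sorted(p for p in root.iterdir() if p.is_dir()):
        tree_path = ddir / "tree.nwk"
        if not tree_path.exists():
            continue
        tree = read_newick(tree_path)
        seqs = read_fasta(ddir / "ssu.fna")
        tables: dict[str, TraitTable] = {}
        for tpath in sorted(ddir.glob("traits_*.tsv*")):
            fw = tpath.name[len("traits_"):].split(".tsv")[0]
            tables[fw] = read_trait_table(tpath, fw)
        ref = DomainReference(
            domain=ddir.name, tree=tree, trait_tables=tables, ssu_sequences=seqs
        )
        ref.validate()
        domains[ddir.name] = ref
    if not domains:
        raise FileNotFoundError(f"no domain directories with tree.nwk under {root}")
    return ReferenceDatabase(domains=domains, manifest=manifest)
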
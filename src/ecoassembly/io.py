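"""File I/O and cross-file validation.

Formats: TSV for tables/metadata/distance matrices, Newick for trees, JSON/YAML
for results and configuration. Distance matrices are serialized as full labeled
square TSV (scikit-bio's lsmat format) for human inspection.
"""

from __future__ import annotations

import collections

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from ecoassembly.containers import (
    CommunityTable,
    FormatError,
    SampleMetadata,
    ValidationReport,
)


# ---------------------------------------------------------------------------
# community table
# ---------------------------------------------------------------------------

def read_community_table(path) -> CommunityTable:
    """Read a taxa x samples TSV: first column taxon IDs, header row sample IDs."""
    df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate taxon ID: {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"duplicate sample ID: {dup!r}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = df.index[vals.isna()][0]
            raise FormatError(f"non-numeric count at taxon {row!r}, sample {col!r}")
        df[col] = vals
    return CommunityTable.from_dataframe(df)


def write_community_table(table: CommunityTable, path) -> None:
    df = table.to_dataframe()
    df.index.name = "taxon_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------

def read_tree(path) -> TreeNode:
    """Read a rooted Newick tree; every non-root edge must carry a branch length."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:
        raise FormatError(f"unparseable Newick: {exc}") from exc
    return _validate_tree(tree)


def _validate_tree(tree: TreeNode) -> TreeNode:
    names = [t.name for t in tree.tips()]
    dup = [n for n, c in collections.Counter(names).items() if c > 1]
    if dup:
        raise FormatError(f"duplicate tree tips: {sorted(dup)}")
    if None in names:
        raise FormatError("unnamed tree tip")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise FormatError(f"missing branch length on edge above {node.name or 'internal node'}")
        if node.length < 0:
            raise FormatError(f"negative branch length above {node.name or 'internal node'}")
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def read_metadata(path) -> SampleMetadata:
    """Read sample metadata TSV: first column sample ID."""
    df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate sample ID: {dup!r}")
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    df = meta.frame.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# distance matrix
# ---------------------------------------------------------------------------

def read_distance_matrix(path) -> DistanceMatrix:
    return DistanceMatrix.read(str(path), format="lsmat")


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    dm.write(str(path), format="lsmat")


# ---------------------------------------------------------------------------
# cross-file validation
# ---------------------------------------------------------------------------

def validate_dataset(table: CommunityTable, tree: TreeNode = None,
                     meta: SampleMetadata = None) -> ValidationReport:
    """Check cross-file consistency of a loaded dataset.

    Side-effect free. Fatal issues: table taxa absent from the tree (breaks
    phylogenetic operations) and table samples absent from the metadata (breaks
    grouped operations). Tree tips not in the table are benign — they are
    pruned before distance computation.
    """
    report = ValidationReport()
    if table.n_samples < 2 or table.n_taxa < 2:
        report.warnings.append(
            f"table has {table.n_taxa} taxa x {table.n_samples} samples; "
            "pairwise analyses need at least 2 of each"
        )
    if tree is not None:
        tips = {t.name for t in tree.tips()}
        missing = [t for t in table.taxon_ids if t not in tips]
        for t in missing:
            report.fatal.append(f"taxon not in tree: {t}")
        extra = len(tips) - (len(table.taxon_ids) - len(missing))
        if extra > 0:
            report.info.append(f"prunable extra tips: {extra}")
    if meta is not None:
        known = set(meta.sample_ids)
        for s in table.sample_ids:
            if s not in known:
                report.fatal.append(f"sample not in metadata: {s}")
        extra_samples = known - set(table.sample_ids)
        if extra_samples:
            report.info.append(f"metadata samples not in table: {len(extra_samples)}")
    return report


# ---------------------------------------------------------------------------
# taxon -> function aggregation
# ---------------------------------------------------------------------------

def read_function_rules(path) -> dict:
    """Read a two-column TSV (taxon_id, function) into a taxon -> [functions] map."""
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] < 2:
        raise FormatError("function rules need two columns: taxon_id, function")
    rules: dict = {}
    for taxon, func in zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)):
        rules.setdefault(taxon, []).append(func)
    return rules


def map_functions(table: CommunityTable, rules: dict) -> pd.DataFrame:
    """Aggregate taxon relative abundances into a function x sample matrix.

    ``rules`` maps taxon IDs to one or more function labels (a generic
    user-supplied mapping; building such a catalogue, e.g. from FAPROTAX, is
    outside this package). A taxon may contribute to several functions; taxa
    without a rule contribute to none.
    """
    if not rules:
        raise FormatError("empty function rules")
    norm = {
        t: ([fs] if isinstance(fs, str) else list(fs)) for t, fs in rules.items()
    }
    functions = sorted({f for fs in norm.values() for f in fs})
    rel = table.relative_abundance()
    out = np.zeros((len(functions), table.n_samples))
    fidx = {f: i for i, f in enumerate(functions)}
    for ti, taxon in enumerate(table.taxon_ids):
        for f in norm.get(taxon, ()):
            out[fidx[f]] += rel[ti]
    return pd.DataFrame(out, index=functions, columns=table.sample_ids)
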
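"""Readers and writers for the external formats the pipeline touches.

Supported formats: tab-separated OTU tables, BIOM v1.0 JSON (dense and
sparse), newick trees (via scikit-bio), tab-separated reaction records, and
tab-separated / JSON result files.  Parsers reject malformed input with a
located error rather than coercing.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import skbio
from skbio import DistanceMatrix, TreeNode

from ._errors import DomainError, FormatError
from .containers import OtuTable, ReactionRecord, SampleMetadata, SampleRecord

FLOAT_FORMAT = "%.6g"


# ---------------------------------------------------------------------------
# OTU tables
# ---------------------------------------------------------------------------

def read_otu_table(path: str | Path, dialect: str = "tsv") -> OtuTable:
    """Read a taxa-by-samples count table.

    ``dialect="tsv"``: first row sample ids, first column taxon ids, integer
    cells.  ``dialect="biom_json"``: BIOM v1.0 JSON, dense or sparse.
    Row/column order is preserved from the file.
    """
    path = Path(path)
    if dialect == "tsv":
        return _read_otu_tsv(path)
    if dialect == "biom_json":
        return _read_biom_json(path)
    raise DomainError(f"unknown dialect {dialect!r}")


def _read_otu_tsv(path: Path) -> OtuTable:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        raise FormatError(f"{path}: duplicate sample ids")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    taxa = [str(t) for t in df.index]
    samples = [str(s) for s in header]
    if len(set(taxa)) != len(taxa):
        raise FormatError(f"{path}: duplicate taxon ids")
    if len(set(samples)) != len(samples):
        raise FormatError(f"{path}: duplicate sample ids")
    counts = np.empty(df.shape, dtype=np.int64)
    for j, s in enumerate(samples):
        for i, t in enumerate(taxa):
            cell = df.iat[i, j]
            try:
                value = int(cell)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-integer count {cell!r} at taxon {t!r}, "
                    f"sample {s!r}"
                ) from None
            if value < 0:
                raise FormatError(
                    f"{path}: negative count {value} at taxon {t!r}, "
                    f"sample {s!r}"
                )
            counts[i, j] = value
    return OtuTable(taxa, samples, counts)


def _read_biom_json(path: Path) -> OtuTable:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON ({exc})") from None
    for key in ("rows", "columns", "shape", "data", "matrix_type"):
        if key not in doc:
            raise FormatError(f"{path}: BIOM document missing {key!r}")
    taxa = [str(r["id"]) for r in doc["rows"]]
    samples = [str(c["id"]) for c in doc["columns"]]
    nrow, ncol = doc["shape"]
    if len(taxa) != nrow or len(samples) != ncol:
        raise FormatError(f"{path}: shape {doc['shape']} disagrees with ids")
    counts = np.zeros((nrow, ncol), dtype=np.int64)
    if doc["matrix_type"] == "sparse":
        for triple in doc["data"]:
            i, j, v = triple
            if v != int(v):
                raise FormatError(
                    f"{path}: non-integer count {v!r} at row {i}, column {j}"
                )
            counts[int(i), int(j)] = int(v)
    elif doc["matrix_type"] == "dense":
        arr = np.asarray(doc["data"])
        if arr.shape != (nrow, ncol):
            raise FormatError(f"{path}: dense data shape mismatch")
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise FormatError(f"{path}: non-integer counts in dense data")
        counts = arr.astype(np.int64)
    else:
        raise FormatError(f"{path}: unknown matrix_type {doc['matrix_type']!r}")
    if np.any(counts < 0):
        raise FormatError(f"{path}: negative counts")
    return OtuTable(taxa, samples, counts)


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(path, sep="\t", index_label="#OTU ID")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> SampleMetadata:
    """Read a sample metadata table (sample_id, community_type, bed_id, site_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "community_type", "bed_id", "site_id"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    records = [
        SampleRecord(
            sample_id=row.sample_id,
            community_type=row.community_type,
            bed_id=row.bed_id,
            site_id=row.site_id,
        )
        for row in df.itertuples()
    ]
    return SampleMetadata(records)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    metadata.to_dataframe().to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> TreeNode:
    """Parse a newick string into a rooted :class:`skbio.TreeNode`.

    Unlabeled internal nodes are permitted; internal labels are preserved.
    Raises :class:`FormatError` for malformed text or negative branch lengths.
    """
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise FormatError(
            f"newick must end with ';' (character {len(stripped)})"
        )
    if stripped.count("(") != stripped.count(")"):
        raise FormatError(
            f"unbalanced parentheses: {stripped.count('(')} '(' vs "
            f"{stripped.count(')')} ')'"
        )
    try:
        # keep underscores literal: OTU ids commonly contain them
        tree = TreeNode.read(
            _io.StringIO(stripped), format="newick", convert_underscores=False
        )
    except Exception as exc:  # skbio raises several parser error types
        raise FormatError(f"newick parse error: {exc}") from None
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            raise FormatError(
                f"negative branch length {node.length} at node "
                f"{node.name or '<unnamed>'}"
            )
    tips = [t.name for t in tree.tips()]
    if len(set(tips)) != len(tips):
        raise FormatError("duplicate tip labels")
    return tree


def read_newick(path: str | Path) -> TreeNode:
    return parse_newick(Path(path).read_text())


def write_newick(tree: TreeNode, path: str | Path) -> None:
    Path(path).write_text(str(tree))


# ---------------------------------------------------------------------------
# Reaction records
# ---------------------------------------------------------------------------

def read_reactions(path: str | Path) -> list[ReactionRecord]:
    """Read tab-separated reaction records.

    Columns: reaction_id, ";"-joined substrates, ";"-joined products,
    reversible flag (0/1).  An optional leading otu_id column (5 columns
    total) keys reactions by organism; see :func:`read_reactions_by_otu`.
    """
    records = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 4:
            raise FormatError(
                f"{path}:{lineno}: expected 4 tab-separated fields, "
                f"got {len(fields)}"
            )
        records.append(_parse_reaction_fields(fields, f"{path}:{lineno}"))
    return records


def read_reactions_by_otu(path: str | Path) -> dict[str, list[ReactionRecord]]:
    """Read a combined reaction file keyed by otu_id (5 columns)."""
    by_otu: dict[str, list[ReactionRecord]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 5:
            raise FormatError(
                f"{path}:{lineno}: expected 5 tab-separated fields "
                f"(otu_id first), got {len(fields)}"
            )
        by_otu.setdefault(fields[0], []).append(
            _parse_reaction_fields(fields[1:], f"{path}:{lineno}")
        )
    return by_otu


def _parse_reaction_fields(fields: list[str], where: str) -> ReactionRecord:
    rid, subs, prods, rev = fields
    substrates = frozenset(s for s in subs.split(";") if s)
    products = frozenset(p for p in prods.split(";") if p)
    if not substrates:
        raise FormatError(f"{where}: reaction {rid!r} has empty substrates")
    if not products:
        raise FormatError(f"{where}: reaction {rid!r} has empty products")
    if rev not in ("0", "1"):
        raise FormatError(f"{where}: reversible flag must be 0 or 1, got {rev!r}")
    return ReactionRecord(rid, substrates, products, rev == "1")


def write_reactions(
    records: list[ReactionRecord] | dict[str, list[ReactionRecord]],
    path: str | Path,
) -> None:
    lines = []
    if isinstance(records, dict):
        for otu_id, recs in records.items():
            for r in recs:
                lines.append(
                    "\t".join(
                        [
                            otu_id,
                            r.reaction_id,
                            ";".join(sorted(r.substrates)),
                            ";".join(sorted(r.products)),
                            "1" if r.reversible else "0",
                        ]
                    )
                )
    else:
        for r in records:
            lines.append(
                "\t".join(
                    [
                        r.reaction_id,
                        ";".join(sorted(r.substrates)),
                        ";".join(sorted(r.products)),
                        "1" if r.reversible else "0",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Distance matrices and generic results
# ---------------------------------------------------------------------------

def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        path, sep="\t", float_format=FLOAT_FORMAT, index_label=""
    )


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    data = df.to_numpy(dtype=float)
    # symmetrize away printed-precision asymmetry before validation
    data = (data + data.T) / 2.0
    np.fill_diagonal(data, 0.0)
    return DistanceMatrix(data, [str(i) for i in df.index])


def write_results(results, path: str | Path) -> None:
    """Write a stage output: DataFrames as tsv, mappings as JSON.

    Column order is deterministic; floats use 6 significant digits.
    """
    path = Path(path)
    if isinstance(results, pd.DataFrame):
        results.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)
    elif isinstance(results, DistanceMatrix):
        write_distance_matrix(results, path)
    elif isinstance(results, dict):
        with open(path, "w") as fh:
            json.dump(results, fh, indent=2, sort_keys=True, default=_jsonify)
            fh.write("\n")
    else:
        raise DomainError(f"cannot serialize {type(results).__name__}")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj).__name__}")
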
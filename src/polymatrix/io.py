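"""Shared file-format readers and writers.

FASTA goes through Biopython's SeqIO, trees through dendropy; the small
text formats the pipeline owns (scoring matrices, partition files, trait
tables) are read and written here so every stage shares one dialect.

Coordinates are 0-based half-open everywhere in memory; exported partition
files use the 1-based inclusive convention of the ML tools that consume
them.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into an ordered list of (id, sequence) pairs.

    Sequence case is preserved verbatim. An empty file yields an empty
    list. Malformed records raise ``ValueError``.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    with open(path) as handle:
        first = handle.read(1)
        if not first:
            return []
        if first != ">":
            raise ValueError(f"{path}: line 1: expected '>' header, got {first!r}")
        handle.seek(0)
        for rec in SeqIO.parse(handle, "fasta"):
            records.append((rec.description, str(rec.seq)))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    """Write (id, sequence) pairs as FASTA, wrapping at ``width`` columns."""
    path = Path(path)
    with open(path, "w") as handle:
        for name, seq in records:
            handle.write(f">{name}\n")
            if width <= 0:
                handle.write(seq + "\n")
            else:
                for i in range(0, max(len(seq), 1), width):
                    handle.write(seq[i : i + width] + "\n")


def fasta_to_seqrecords(records: Iterable[tuple[str, str]]) -> list[SeqRecord]:
    return [SeqRecord(Seq(s), id=n, description="") for n, s in records]


# ---------------------------------------------------------------------------
# Newick trees

#: Support-value dialects: bootstrap stored as internal-node labels
#: ("(A,B)95:0.1") or as branch comments ("(A,B):0.1[95]").
NEWICK_DIALECTS = ("support-as-internal-label", "support-as-branch-comment")


def read_newick(
    source: str | Path,
    dialect: str = "support-as-internal-label",
    rooting: str = "default-rooted",
) -> dendropy.Tree:
    """Parse a Newick tree, interpreting supports per ``dialect``.

    Duplicate tip labels raise ``ValueError``. Internal node labels that
    parse as numbers are recorded as edge supports under the default
    dialect; non-numeric labels are kept as node labels.
    """
    if dialect not in NEWICK_DIALECTS:
        raise ValueError(f"unknown Newick dialect: {dialect}")
    # Accept either a path or a literal newick string.
    src = str(source)
    if "(" in src and ";" in src:
        data, kind = src, "data"
    else:
        data, kind = str(Path(source)), "path"
    try:
        if kind == "data":
            tree = dendropy.Tree.get(data=data, schema="newick", rooting=rooting,
                                     suppress_internal_node_taxa=True)
        else:
            tree = dendropy.Tree.get(path=data, schema="newick", rooting=rooting,
                                     suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"failed to parse Newick from {source!r}: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    if dialect == "support-as-internal-label":
        for node in tree.preorder_node_iter():
            if not node.is_leaf() and node.label is not None:
                try:
                    node.edge.head_node.support = float(node.label)  # type: ignore[attr-defined]
                except ValueError:
                    pass
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    """Serialise a tree to Newick (supports as internal-node labels)."""
    text = tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True).strip()
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


# ---------------------------------------------------------------------------
# Scoring-matrix text format (BLOSUM-style)


def write_score_matrix(
    residues: Sequence[str],
    scores: np.ndarray,
    path: str | Path,
    metadata: Mapping[str, object] | None = None,
) -> None:
    """Write a whitespace-delimited scoring matrix readable by FASTA/EMBOSS.

    Header comment lines are prefixed with '#'; then a header row of
    residues and one labeled row per residue.
    """
    lines = []
    for key, value in (metadata or {}).items():
        lines.append(f"# {key}: {value}")
    lines.append("   " + "  ".join(f"{r:>2}" for r in residues))
    for i, r in enumerate(residues):
        row = "  ".join(f"{int(scores[i, j]):>2}" for j in range(len(residues)))
        lines.append(f"{r}  {row}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_score_matrix(path: str | Path) -> tuple[list[str], np.ndarray, dict[str, str]]:
    """Read the scoring-matrix format written by :func:`write_score_matrix`."""
    metadata: dict[str, str] = {}
    residues: list[str] = []
    rows: list[list[int]] = []
    for line in Path(path).read_text().splitlines():
        line = line.rstrip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                metadata[k.strip()] = v.strip()
            continue
        parts = line.split()
        if not residues:
            residues = parts
        else:
            rows.append([int(x) for x in parts[1:]])
    return residues, np.array(rows, dtype=int), metadata


# ---------------------------------------------------------------------------
# Relaxed PHYLIP


def write_phylip(rows: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Write a relaxed PHYLIP alignment (names of any length, one space)."""
    if not rows:
        raise ValueError("empty alignment")
    n, width = len(rows), len(rows[0][1])
    pad = max(len(name) for name, _ in rows) + 2
    with open(path, "w") as handle:
        handle.write(f"{n} {width}\n")
        for name, seq in rows:
            handle.write(f"{name:<{pad}}{seq}\n")


def read_phylip(path: str | Path) -> list[tuple[str, str]]:
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    n, width = (int(x) for x in lines[0].split())
    rows = []
    for line in lines[1 : n + 1]:
        name, seq = line.split(None, 1)
        seq = seq.replace(" ", "")
        if len(seq) != width:
            raise ValueError(f"row {name}: length {len(seq)} != header width {width}")
        rows.append((name, seq))
    return rows


# ---------------------------------------------------------------------------
# Trait tables


def read_trait_csv(path: str | Path) -> dict[str, str]:
    """Read a two-column (taxon,state) CSV; a header row is optional."""
    out: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line:
            continue
        taxon, state = (x.strip() for x in line.split(",", 1))
        if i == 0 and taxon.lower() in {"taxon", "tip", "species"}:
            continue
        out[taxon] = state
    return out


def write_trait_csv(traits: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("taxon,state\n")
        for taxon in traits:
            handle.write(f"{taxon},{traits[taxon]}\n")


# ---------------------------------------------------------------------------
# Config


def load_config(path: str | Path) -> dict:
    with open(path) as handle:
        data = yaml.safe_load(handle)
    return data or {}


def dump_config(config: Mapping, path: str | Path) -> None:
    with open(path, "w") as handle:
        yaml.safe_dump(dict(config), handle, sort_keys=True)
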
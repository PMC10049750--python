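"""Codon back-translation, concatenation, column filtering and statistics.

Protein alignments are converted to codon alignments by substituting each
residue's source codon (and each protein gap by ``---``), concatenated in
stable lexicographic group order into a taxon-by-site supermatrix with a
gene coordinate map, filtered by the minimum-taxon codon rule, and
summarised (completeness, ambiguity, per-taxon aligned bp). Export writes
FASTA, relaxed PHYLIP and a codon-position partition file in the 1-based
``start-end\\3`` stride convention of the ML tools that consume them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from Bio.Seq import Seq

from . import io as pio

GAP_CHARS = {"-", "?"}
#: IUPAC ambiguity codes counted as ambiguous cells in stats (gaps are not).
AMBIGUOUS_NUC = set("NRYSWKMBDHV")


@dataclass
class CodonAlignment:
    """Per-group codon alignment; width = 3 x protein alignment width."""

    group_id: str
    rows: dict[str, str]  # taxon -> nucleotide sequence with '-' gaps

    def __post_init__(self) -> None:
        widths = {len(s) for s in self.rows.values()}
        if len(widths) > 1:
            raise ValueError(f"{self.group_id}: unequal row lengths {widths}")
        if widths and next(iter(widths)) % 3:
            raise ValueError(f"{self.group_id}: width not divisible by 3")

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0


@dataclass
class SuperMatrix:
    """Concatenated codon matrix with gene coordinates and partitions."""

    rows: dict[str, str]  # taxon -> full-length sequence
    coordinates: dict[str, tuple[int, int]]  # group -> [start, end) columns

    @property
    def taxa(self) -> list[str]:
        return sorted(self.rows)

    @property
    def n_sites(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0


@dataclass
class MatrixStats:
    n_groups: int
    n_sites: int
    percent_complete: float
    percent_ambiguous: float
    per_taxon_bp: dict[str, int] = field(default_factory=dict)
    per_taxon_fraction: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Back-translation


def backtranslate(
    protein_alignment: Mapping[str, str],
    cds: Mapping[str, str],
    group_id: str = "group",
) -> CodonAlignment:
    """Replace each aligned residue by its source codon, gaps by ``---``.

    Each taxon's ungapped protein row must equal the translation of its
    CDS (a trailing stop codon is tolerated and trimmed); mismatches
    raise with the taxon and first offending residue named.
    """
    rows: dict[str, str] = {}
    for taxon, prot in protein_alignment.items():
        ungapped = prot.replace("-", "")
        if not ungapped:
            rows[taxon] = "-" * (3 * len(prot))
            continue
        if taxon not in cds:
            raise ValueError(f"{group_id}: no CDS for taxon {taxon!r}")
        nuc = cds[taxon].upper()
        if len(nuc) % 3:
            raise ValueError(f"{group_id}/{taxon}: CDS length {len(nuc)} not divisible by 3")
        translated = str(Seq(nuc).translate())
        if translated.endswith("*"):
            translated = translated[:-1]
            nuc = nuc[:-3]
        if len(nuc) != 3 * len(ungapped):
            raise ValueError(
                f"{group_id}/{taxon}: CDS codes {len(translated)} residues, "
                f"protein row has {len(ungapped)}"
            )
        for k, (a, b) in enumerate(zip(ungapped, translated)):
            if a != b and a != "X" and b != "X":
                raise ValueError(
                    f"{group_id}/{taxon}: protein/CDS mismatch at residue {k}: "
                    f"{a!r} vs translated {b!r}"
                )
        out = []
        pos = 0
        for residue in prot:
            if residue == "-":
                out.append("---")
            else:
                out.append(nuc[3 * pos : 3 * pos + 3])
                pos += 1
        rows[taxon] = "".join(out)
    return CodonAlignment(group_id=group_id, rows=rows)


# ---------------------------------------------------------------------------
# Concatenation and filtering


def concatenate(
    alignments: Sequence[CodonAlignment], taxon_set: Sequence[str]
) -> SuperMatrix:
    """Append groups in sorted-group-id order, gap-filling absent taxa."""
    taxa = list(taxon_set)
    extra = {t for a in alignments for t in a.rows} - set(taxa)
    if extra:
        raise ValueError(f"alignment taxa outside taxon_set: {sorted(extra)}")
    ids = [a.group_id for a in alignments]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate group ids")
    parts: dict[str, list[str]] = {t: [] for t in taxa}
    coordinates: dict[str, tuple[int, int]] = {}
    offset = 0
    for aln in sorted(alignments, key=lambda a: a.group_id):
        width = aln.width
        coordinates[aln.group_id] = (offset, offset + width)
        for taxon in taxa:
            parts[taxon].append(aln.rows.get(taxon, "-" * width))
        offset += width
    return SuperMatrix(
        rows={t: "".join(parts[t]) for t in taxa}, coordinates=coordinates
    )


def _codon_has_data(triple: str) -> bool:
    return any(c not in GAP_CHARS and c not in AMBIGUOUS_NUC for c in triple)


def filter_codon_columns(matrix: SuperMatrix, min_taxa: int = 4) -> SuperMatrix:
    """Drop codon triples with unambiguous data in fewer than ``min_taxa`` taxa.

    A taxon represents a codon if the triple contains at least one
    unambiguous, non-gap nucleotide. The gene coordinate map is
    re-indexed onto the surviving columns.
    """
    n = matrix.n_sites
    if n % 3:
        raise ValueError("matrix width not divisible by 3")
    taxa = matrix.taxa
    keep: list[int] = []
    for c in range(0, n, 3):
        count = sum(1 for t in taxa if _codon_has_data(matrix.rows[t][c : c + 3]))
        if count >= min_taxa:
            keep.append(c)
    keep_set = set(keep)
    rows = {
        t: "".join(matrix.rows[t][c : c + 3] for c in keep) for t in taxa
    }
    coordinates: dict[str, tuple[int, int]] = {}
    offset = 0
    for group, (start, end) in sorted(matrix.coordinates.items(), key=lambda kv: kv[1][0]):
        surviving = sum(3 for c in range(start, end, 3) if c in keep_set)
        coordinates[group] = (offset, offset + surviving)
        offset += surviving
    return SuperMatrix(rows=rows, coordinates=coordinates)


# ---------------------------------------------------------------------------
# Statistics


def matrix_stats(matrix: SuperMatrix) -> MatrixStats:
    """Completeness, ambiguity and per-taxon aligned bp.

    Completeness counts non-gap cells ('-' and '?' are gaps); ambiguity
    counts N and partial IUPAC codes, which are also non-gap (so they
    count toward completeness). Percentages are over all cells.
    """
    taxa = matrix.taxa
    n_sites = matrix.n_sites
    n_cells = len(taxa) * n_sites
    if n_cells == 0:
        return MatrixStats(
            n_groups=len(matrix.coordinates), n_sites=0,
            percent_complete=0.0, percent_ambiguous=0.0,
            per_taxon_bp={t: 0 for t in taxa},
            per_taxon_fraction={t: 0.0 for t in taxa},
        )
    non_gap = 0
    ambiguous = 0
    per_bp: dict[str, int] = {}
    for t in taxa:
        row = matrix.rows[t]
        bp = sum(1 for c in row if c not in GAP_CHARS)
        amb = sum(1 for c in row if c in AMBIGUOUS_NUC)
        per_bp[t] = bp
        non_gap += bp
        ambiguous += amb
    return MatrixStats(
        n_groups=len(matrix.coordinates),
        n_sites=n_sites,
        percent_complete=100.0 * non_gap / n_cells,
        percent_ambiguous=100.0 * ambiguous / n_cells,
        per_taxon_bp=per_bp,
        per_taxon_fraction={t: per_bp[t] / n_sites for t in taxa},
    )


# ---------------------------------------------------------------------------
# Export / import


def partition_lines(matrix: SuperMatrix) -> list[str]:
    """Codon-position partitions in 1-based inclusive stride notation.

    Three partitions (pos1/pos2/pos3); each lists a ``start-end\\3``
    stride per gene range so partition boundaries follow gene boundaries.
    """
    strides: dict[int, list[str]] = {0: [], 1: [], 2: []}
    for group, (start, end) in sorted(matrix.coordinates.items(), key=lambda kv: kv[1][0]):
        if end <= start:
            continue
        for pos in range(3):
            strides[pos].append(f"{start + pos + 1}-{end}\\3")
    return [
        f"DNA, pos{pos + 1} = " + ", ".join(strides[pos])
        for pos in range(3)
        if strides[pos]
    ]


def export(matrix: SuperMatrix, out_dir: str | Path, formats: Sequence[str] = ("fasta", "phylip", "partitions", "stats")) -> dict[str, Path]:
    """Write the supermatrix and its companions; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    rows = [(t, matrix.rows[t]) for t in matrix.taxa]
    if "fasta" in formats:
        p = out_dir / "supermatrix.fasta"
        pio.write_fasta(rows, p)
        written["fasta"] = p
    if "phylip" in formats:
        p = out_dir / "supermatrix.phy"
        pio.write_phylip(rows, p)
        written["phylip"] = p
    if "partitions" in formats:
        p = out_dir / "partitions.txt"
        p.write_text("\n".join(partition_lines(matrix)) + "\n")
        written["partitions"] = p
    # coordinates are always written: the FASTA alone cannot round-trip
    if True:
        p = out_dir / "gene_coordinates.tsv"
        with open(p, "w") as fh:
            fh.write("group\tstart\tend\n")
            for g, (s, e) in sorted(matrix.coordinates.items()):
                fh.write(f"{g}\t{s}\t{e}\n")
        written["coordinates"] = p
    if "stats" in formats:
        stats = matrix_stats(matrix)
        p = out_dir / "matrix_stats.tsv"
        with open(p, "w") as fh:
            fh.write("taxon\taligned_bp\tfraction_of_full_length\n")
            for t in matrix.taxa:
                fh.write(f"{t}\t{stats.per_taxon_bp[t]}\t{stats.per_taxon_fraction[t]:.4f}\n")
            fh.write(f"#n_groups\t{stats.n_groups}\n")
            fh.write(f"#n_sites\t{stats.n_sites}\n")
            fh.write(f"#percent_complete\t{stats.percent_complete:.4f}\n")
            fh.write(f"#percent_ambiguous\t{stats.percent_ambiguous:.4f}\n")
        written["stats"] = p
    return written


def import_supermatrix(fasta_path: str | Path, coordinates_path: str | Path) -> SuperMatrix:
    """Re-read an exported supermatrix bit-exactly."""
    rows = dict(pio.read_fasta(fasta_path))
    coordinates: dict[str, tuple[int, int]] = {}
    for line in Path(coordinates_path).read_text().splitlines()[1:]:
        if not line.strip():
            continue
        group, start, end = line.split("\t")
        coordinates[group] = (int(start), int(end))
    return SuperMatrix(rows=rows, coordinates=coordinates)
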
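"""Readers and writers for the formats the toolkit touches.

FASTA parsing is delegated to Bio.SeqIO, Newick to dendropy, tabular data to
pandas; this module adds the validation the pipeline relies on (unique ids,
rooted trees, rectangular matrices) and keeps all coordinates 0-based
half-open.  BED output is native 0-based half-open.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .model import (
    FormatError,
    Phylogeny,
    SequenceRecord,
    TipStateMatrix,
    unique_ids,
)

_STATE_FROM_CELL = {"1": "present", "0": "absent", "?": "unknown"}
_CELL_FROM_STATE = {"present": "1", "absent": "0", "unknown": "?"}


def read_fasta(path: str | Path, alphabet: str = "dna") -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords (residues upper-cased).

    Raises FormatError naming the offending line for an empty file, a file
    not starting with a header, or duplicate ids.
    """
    path = Path(path)
    text = path.read_text()
    first_content = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            first_content = (lineno, line)
            break
    if first_content is None:
        raise FormatError(f"{path}: empty FASTA file (line 1)")
    if not first_content[1].startswith(">"):
        raise FormatError(
            f"{path}: line {first_content[0]} does not start a FASTA header"
        )
    records = [
        SequenceRecord(
            id=rec.id,
            alphabet=alphabet,  # type: ignore[arg-type]
            residues=str(rec.seq),
            description=rec.description[len(rec.id):].strip(),
        )
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    unique_ids(records)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def read_newick(path: str | Path) -> Phylogeny:
    """Read a single rooted Newick tree; reject a trifurcating root."""
    return Phylogeny.from_newick(Path(path).read_text())


def write_newick(phy: Phylogeny, path: str | Path) -> None:
    Path(path).write_text(phy.to_newick() + "\n")


def read_state_matrix(path: str | Path) -> TipStateMatrix:
    """Read a TSV presence/absence matrix (rows taxa, columns genes).

    Cells are 1 (present), 0 (absent) or ? (unknown); the first header
    column names the taxon id column.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty matrix file")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: header row must name at least one gene")
    genes = header[1:]
    taxa: list[str] = []
    state: dict[tuple[str, str], str] = {}
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        if len(cells) != len(header):
            raise FormatError(
                f"{path}: line {lineno} has {len(cells)} fields, "
                f"expected {len(header)} (ragged row)"
            )
        taxon = cells[0]
        taxa.append(taxon)
        for gene, cell in zip(genes, cells[1:]):
            if cell not in _STATE_FROM_CELL:
                raise FormatError(
                    f"{path}: line {lineno}: cell {cell!r} not in 1/0/?"
                )
            state[(taxon, gene)] = _STATE_FROM_CELL[cell]
    return TipStateMatrix(taxa, genes, state)  # type: ignore[arg-type]


def write_state_matrix(matrix: TipStateMatrix, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("taxon\t" + "\t".join(matrix.genes) + "\n")
        for taxon in matrix.taxa:
            cells = [_CELL_FROM_STATE[matrix[(taxon, g)]] for g in matrix.genes]
            fh.write(taxon + "\t" + "\t".join(cells) + "\n")


def read_bed_starts(path: str | Path) -> dict[str, list[int]]:
    """Read a BED file, returning sorted start coordinates per contig."""
    starts: dict[str, list[int]] = {}
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        if not ln.strip() or ln.startswith(("#", "track", "browser")):
            continue
        fields = ln.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}: line {lineno}: BED needs >= 3 fields")
        starts.setdefault(fields[0], []).append(int(fields[1]))
    return {contig: sorted(pos) for contig, pos in starts.items()}


def write_bed(intervals: Sequence[tuple[str, int, int, str]],
              path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for contig, start, end, name in intervals:
            fh.write(f"{contig}\t{start}\t{end}\t{name}\n")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=str) + "\n")


def read_counts_table(path: str | Path) -> pd.DataFrame:
    """Read a gene,pS,pN,dS,dN TSV for batch MK analysis."""
    df = pd.read_csv(path, sep="\t")
    required = ["gene", "pS", "pN", "dS", "dN"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if (df[["pS", "pN", "dS", "dN"]] < 0).any().any():
        raise FormatError(f"{path}: negative counts are not allowed")
    return df[required]
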
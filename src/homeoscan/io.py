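"""Shared file-format I/O for the pipeline.

All on-disk formats are plain text: FASTA (nucleotide and protein, read via
Biopython), tab-separated tables with ``#`` comment lines (pandas), and Newick
trees (dendropy).  Writers aim for round-trip stability: ``write(read(x))``
produces a canonical file that re-reads to the identical object.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import dendropy
import pandas as pd
from Bio import SeqIO


class FormatError(ValueError):
    """Raised on malformed input files, with location information."""


_NT_CHARS = set("ACGTUNRYSWKMBDHV")
_AA_CHARS = set("ACDEFGHIKLMNPQRSTVWYBXZJUO*")


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide or protein sequence with a species tag.

    ``id`` follows the convention ``Species|rest...``; ``species`` holds the
    first ``|``-separated field (or the full id if there is none).
    """

    id: str
    residues: str
    alphabet: str = "aa"  # "nt" or "aa"
    species: str = ""

    def __post_init__(self):
        if not self.residues:
            raise FormatError(f"empty sequence for record {self.id!r}")
        if self.alphabet not in ("nt", "aa"):
            raise FormatError(f"unknown alphabet {self.alphabet!r}")
        allowed = _NT_CHARS if self.alphabet == "nt" else _AA_CHARS
        bad = [i for i, c in enumerate(self.residues.upper()) if c not in allowed and c != "-"]
        if bad:
            raise FormatError(
                f"record {self.id!r}: non-IUPAC {self.alphabet} characters at positions "
                + ", ".join(str(i) for i in bad[:10])
                + ("..." if len(bad) > 10 else "")
            )
        if not self.species:
            object.__setattr__(self, "species", self.id.split("|")[0])

    def __len__(self) -> int:
        return len(self.residues)


def guess_alphabet(seq: str) -> str:
    letters = set(seq.upper()) - {"-"}
    if letters <= _NT_CHARS:
        return "nt"
    return "aa"


def read_fasta(path, alphabet: str | None = None) -> list[SequenceRecord]:
    """Read a FASTA file strictly: unique non-empty ids, non-empty sequences.

    Tolerates CRLF line endings and arbitrary line wrapping.  ``alphabet`` may
    be forced; otherwise it is guessed per record.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: FASTA record with empty id")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(
            SequenceRecord(rec.id, seq, alphabet or guess_alphabet(seq))
        )
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_tsv(path, **kwargs) -> pd.DataFrame:
    """Read a tab-separated table with '#'-prefixed comment lines."""
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False, **kwargs)
    except pd.errors.ParserError as exc:  # pragma: no cover - message passthrough
        raise FormatError(f"{path}: {exc}") from exc


def write_tsv(df: pd.DataFrame, path, comment: str | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_newick(path_or_string, rooting: str = "default-unrooted") -> dendropy.Tree:
    """Parse one Newick tree; raises FormatError naming the offending token."""
    try:
        is_path = False
        try:
            is_path = Path(str(path_or_string)).exists()
        except OSError:
            is_path = False
        if is_path:
            tree = dendropy.Tree.get(path=str(path_or_string), schema="newick",
                                     rooting=rooting, preserve_underscores=True,
                                     suppress_internal_node_taxa=True)
        else:
            tree = dendropy.Tree.get(data=str(path_or_string), schema="newick",
                                     rooting=rooting, preserve_underscores=True,
                                     suppress_internal_node_taxa=True)
    except Exception as exc:
        raise FormatError(f"malformed Newick: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise FormatError(f"duplicate leaf ids in tree: {dup}")
    return tree


def write_newick(tree: dendropy.Tree, path=None) -> str:
    s = tree.as_string(schema="newick", suppress_rooting=True,
                       unquoted_underscores=True).strip()
    if path is not None:
        Path(path).write_text(s + "\n")
    return s


_KINDS = ("fasta", "alignedFasta", "newick", "annotatedNewick", "tsvRegistry", "tsvMatrix")


def parse_formats(path, kind: str):
    """Dispatch strict parsing by file kind (see spec of supported kinds)."""
    if kind not in _KINDS:
        raise ValueError(f"unknown kind {kind!r}; expected one of {_KINDS}")
    if kind == "fasta":
        return read_fasta(path)
    if kind == "alignedFasta":
        recs = read_fasta(path)
        lengths = {len(r.residues) for r in recs}
        if len(lengths) != 1:
            raise FormatError(f"{path}: alignment rows have unequal lengths {sorted(lengths)}")
        return recs
    if kind == "newick":
        return read_newick(path)
    if kind == "annotatedNewick":
        from .reconcile import read_annotated_newick

        return read_annotated_newick(path)
    if kind == "tsvRegistry":
        from .clades import CladeRegistry

        return CladeRegistry.from_tsv(path)
    if kind == "tsvMatrix":
        df = read_tsv(path)
        df = df.set_index(df.columns[0])
        return df.astype(int).astype(bool)
    raise AssertionError("unreachable")
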
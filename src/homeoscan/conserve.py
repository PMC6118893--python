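"""Alignment-column conservation analyses.

Three figure-style operations: masking identities against a reference row
(differences shown, identities as full stops, gaps never masked), finding
columns where a focal sequence is the only variant (all other rows agree and
are ungapped), and scanning sequences with a log-odds position weight matrix
built from example motif instances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import SequenceRecord
from .njtree import Alignment
from .simulate import AMINO_ACIDS


@dataclass
class IdentityMask:
    reference_id: str
    ids: list[str]
    masked_rows: list[str]

    def unmask(self, row_id: str, reference_row: str) -> str:
        """Reconstruct the original row from its mask and the reference."""
        masked = dict(zip(self.ids, self.masked_rows))[row_id]
        out = []
        for m, r in zip(masked, reference_row):
            out.append(r if m == "." else m)
        return "".join(out)


def identity_mask(alignment: Alignment, reference_id: str) -> IdentityMask:
    """Mark identities to the reference row with '.'; the reference row is
    shown in full.  Gap characters are never masked as identity."""
    if reference_id not in alignment.ids:
        raise KeyError(f"reference {reference_id!r} not in alignment")
    ref = alignment.rows[alignment.ids.index(reference_id)]
    masked = []
    for rid, row in zip(alignment.ids, alignment.rows):
        if rid == reference_id:
            masked.append(row)
            continue
        masked.append("".join(
            "." if (a == b and a != "-") else a for a, b in zip(row, ref)))
    return IdentityMask(reference_id, list(alignment.ids), masked)


def unique_variant_positions(alignment: Alignment, focal_id: str) -> list[int]:
    """Columns where the focal row is the only variant.

    A column qualifies when every non-focal row carries one identical,
    ungapped residue and the focal row differs.  Columns where the focal row
    has a gap, or any non-focal row has a gap, are excluded.
    """
    if focal_id not in alignment.ids:
        raise KeyError(f"focal id {focal_id!r} not in alignment")
    if len(alignment) < 3:
        raise ValueError("need at least 3 rows to define a unique variant")
    focal = alignment.rows[alignment.ids.index(focal_id)]
    others = [r for i, r in zip(alignment.ids, alignment.rows) if i != focal_id]
    out = []
    for col in range(alignment.n_columns):
        residues = {r[col] for r in others}
        if len(residues) != 1 or "-" in residues:
            continue
        (shared,) = residues
        if focal[col] != shared and focal[col] != "-":
            out.append(col)
    return out


# ---------------------------------------------------------------------------
# motif scanning


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    start: int
    end: int
    score: float


@dataclass
class MotifProfile:
    """Log-odds position weight matrix over the 20 amino acids."""

    matrix: np.ndarray  # (width, 20)

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())

    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.matrix.argmax(axis=1))


_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Default acceptance threshold for motif hits (natural-log odds).  Chosen so
#: that random sequences of background composition score a best-window hit at
#: well under a 1% rate for a 12-column profile.
DEFAULT_MOTIF_MIN_SCORE = 8.0


def load_medial_hox_standin() -> Alignment:
    """Load the synthetic medial-Hox homeodomain alignment shipped as data.

    This is a constructed stand-in (no sequence is from a real organism): a
    consensus-derived block of medial-Hox-like rows in which the divergent
    focal row ``Slam_Antp`` is, by construction, the only variant at exactly
    six columns.  It exercises the unique-variant analysis in the shape of
    the published figure without reproducing its data.
    """
    from importlib.resources import files

    path = files("homeoscan.data").joinpath("medial_hox_alignment_synthetic.fasta")
    return Alignment.from_fasta(str(path))


def build_motif_profile(instances: Sequence[str], pseudocount: float = 0.5,
                        background: np.ndarray | None = None) -> MotifProfile:
    """Build a log-odds PWM from equal-length example motif instances.

    Column frequencies receive ``pseudocount`` smoothing; the background is
    uniform unless given.  Scores are natural-log odds.
    """
    if not instances:
        raise ValueError("need at least one motif instance")
    width = len(instances[0])
    if any(len(s) != width for s in instances):
        raise ValueError("motif instances must have equal length")
    counts = np.full((width, 20), pseudocount, dtype=float)
    for seq in instances:
        for pos, aa in enumerate(seq.upper()):
            if aa in _AA_INDEX:
                counts[pos, _AA_INDEX[aa]] += 1.0
    freqs = counts / counts.sum(axis=1, keepdims=True)
    if background is None:
        background = np.full(20, 1.0 / 20)
    return MotifProfile(np.log(freqs / background))


def scan_motif(sequences: Iterable[SequenceRecord], profile: MotifProfile,
               min_score: float) -> list[MotifHit]:
    """Best sliding-window hit per sequence with score >= ``min_score``.

    Sequences shorter than the profile window yield no hit (not an error).
    Positions with residues outside the 20-letter alphabet score zero.
    """
    hits: list[MotifHit] = []
    w = profile.width
    for rec in sequences:
        seq = rec.residues.upper()
        if len(seq) < w:
            continue
        best: MotifHit | None = None
        idx = np.array([_AA_INDEX.get(a, -1) for a in seq])
        for start in range(len(seq) - w + 1):
            window = idx[start : start + w]
            valid = window >= 0
            score = float(profile.matrix[np.arange(w)[valid], window[valid]].sum())
            if best is None or score > best.score:
                best = MotifHit(rec.id, start, start + w, score)
        if best is not None and best.score >= min_score:
            hits.append(best)
    return hits
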
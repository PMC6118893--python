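"""Homeodomain discovery by recursive local-alignment search.

Targets (nucleotide scaffolds or protein sets) are scanned with an exact
affine-gap Smith-Waterman search (Biopython's ``PairwiseAligner``); every
accepted domain is excised and added to the query pool, and the scan repeats
until an iteration discovers nothing new ("search saturation").  Candidate
domains are typed TALE / non-TALE by the three-amino-acid loop extension and
flagged intact, degraded or truncated; per-gene architectures (single, double,
double-with-degraded, fragment) are called from the grouped hits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .io import SequenceRecord
from .simulate import revcomp


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ScanConfig:
    """Search parameters.

    ``acceptScore`` is the minimum Smith-Waterman score (matrix units) for an
    intact hit; candidates scoring in ``[degradedFraction * acceptScore,
    acceptScore)`` are reported as degraded remnants.  A gap of length k costs
    ``gapOpen + k * gapExtend``.  ``flankResidues`` widens excised windows (5
    for Hox/ParaHox mode, 0 otherwise).
    """

    scoringMatrix: str = "BLOSUM62"
    gapOpen: float = 10.0
    gapExtend: float = 1.0
    acceptScore: float = 150.0
    degradedFraction: float = 0.4
    taleMargin: float = 5.0
    maxIterations: int = 10
    flankResidues: int = 0
    overlapLimit: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.acceptScore <= 0:
            raise ConfigError("acceptScore must be > 0")
        if self.maxIterations < 1:
            raise ConfigError("maxIterations must be >= 1")
        if not 0 < self.degradedFraction <= 1:
            raise ConfigError("degradedFraction must be in (0, 1]")

    @property
    def degradedFloor(self) -> float:
        return self.degradedFraction * self.acceptScore


def make_aligner(config: ScanConfig, alphabet: str = "aa") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if alphabet == "aa":
        try:
            matrix = substitution_matrices.load(config.scoringMatrix)
        except FileNotFoundError as exc:
            raise ConfigError(f"unknown scoring matrix {config.scoringMatrix!r}") from exc
        aligner.substitution_matrix = matrix
    else:
        aligner.match_score = 1.0
        aligner.mismatch_score = -2.0
    # affine: gap of length k costs gapOpen + k*gapExtend
    aligner.open_gap_score = -(config.gapOpen + config.gapExtend)
    aligner.extend_gap_score = -config.gapExtend
    return aligner


# ---------------------------------------------------------------------------
# six-frame translation


@dataclass(frozen=True)
class TranslatedFrame:
    source_id: str
    strand: str  # "+" or "-"
    frame: int   # 0, 1, 2 offset on the reading strand
    residues: str
    source_length: int

    def nt_interval(self, aa_start: int, aa_end: int) -> tuple[int, int]:
        """Forward-strand nucleotide coords of an aa interval on this frame."""
        off = self.frame + 3 * aa_start
        end = self.frame + 3 * aa_end
        if self.strand == "+":
            return off, end
        return self.source_length - end, self.source_length - off


def translate_six_frames(record: SequenceRecord) -> list[TranslatedFrame]:
    """Translate all six reading frames with the standard genetic code.

    Stop codons are emitted as ``*``; IUPAC ambiguity codes translate to 'X'.
    """
    if record.alphabet != "nt":
        raise ValueError(f"record {record.id!r} is not nucleotide")
    seq = record.residues.upper()
    frames = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for f in range(3):
            sub = s[f : f + 3 * ((len(s) - f) // 3)]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # partial-codon warnings
                aa = str(Seq(sub).translate())
            frames.append(TranslatedFrame(record.id, strand, f, aa, len(seq)))
    return frames


# ---------------------------------------------------------------------------
# pairwise local alignment


@dataclass(frozen=True)
class LocalAlignment:
    score: float
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    aligned_query: str
    aligned_target: str


def local_align(query: str, target: str, config: ScanConfig) -> LocalAlignment:
    """Optimal Smith-Waterman local alignment of ``query`` against ``target``."""
    if not query or not target:
        raise ValueError("query and target must be non-empty")
    aligner = make_aligner(config)
    aln = aligner.align(target, query)[0]
    t_blocks, q_blocks = aln.aligned
    ts, te = int(t_blocks[0][0]), int(t_blocks[-1][1])
    qs, qe = int(q_blocks[0][0]), int(q_blocks[-1][1])
    a_target, a_query = str(aln[0]), str(aln[1])
    return LocalAlignment(float(aln.score), qs, qe, ts, te, a_query, a_target)


def alignment_score_from_strings(aligned_query: str, aligned_target: str,
                                 config: ScanConfig) -> float:
    """Recompute the score of an alignment from its gapped strings."""
    matrix = substitution_matrices.load(config.scoringMatrix)
    score = 0.0
    in_gap = False
    for q, t in zip(aligned_query, aligned_target):
        if q == "-" or t == "-":
            score -= config.gapExtend + (config.gapOpen if not in_gap else 0.0)
            in_gap = True
        else:
            score += matrix[q, t]
            in_gap = False
    return score


# ---------------------------------------------------------------------------
# TALE typing


def classify_tale(candidate: str, profiles: Mapping[str, str],
                  config: ScanConfig | None = None) -> str:
    """Type a candidate homeodomain by gapped alignment against the 60-aa and
    63-aa reference profiles; ``unresolved`` when the score margin is small."""
    if len(candidate) < 50:
        raise ValueError("candidate too short to type (need >= 50 aa)")
    config = config or ScanConfig()
    aligner = make_aligner(config)
    s_non = float(aligner.score(profiles["nonTALE"], candidate))
    s_tale = float(aligner.score(profiles["TALE"], candidate))
    if abs(s_tale - s_non) < config.taleMargin:
        return "unresolved"
    return "TALE" if s_tale > s_non else "nonTALE"


# ---------------------------------------------------------------------------
# hits


@dataclass(frozen=True)
class HomeodomainHit:
    """A located, scored, typed homeodomain interval on a source sequence.

    Nucleotide coordinates are 0-based half-open on the forward strand;
    ``aa_start``/``aa_end`` are on the translated reading frame (or directly
    on the protein for protein sources, where ``nt_start``/``nt_end`` are
    ``None`` and strand is "+").
    """

    source_id: str
    strand: str
    frame: int
    nt_start: int | None
    nt_end: int | None
    aa_start: int
    aa_end: int
    score: float
    best_query_id: str
    hd_type: str      # TALE / nonTALE / unresolved
    intactness: str   # intact / degraded / truncated
    sequence: str
    iteration: int

    @property
    def aa_length(self) -> int:
        return self.aa_end - self.aa_start


def hits_to_frame(hits: Iterable[HomeodomainHit]) -> pd.DataFrame:
    cols = ["sourceId", "strand", "frame", "ntStart", "ntEnd", "aaStart",
            "aaEnd", "score", "bestQueryId", "hdType", "intactness",
            "iteration", "sequence"]
    rows = [{
        "sourceId": h.source_id, "strand": h.strand, "frame": h.frame,
        "ntStart": "" if h.nt_start is None else h.nt_start,
        "ntEnd": "" if h.nt_end is None else h.nt_end,
        "aaStart": h.aa_start, "aaEnd": h.aa_end, "score": h.score,
        "bestQueryId": h.best_query_id, "hdType": h.hd_type,
        "intactness": h.intactness, "iteration": h.iteration,
        "sequence": h.sequence,
    } for h in hits]
    return pd.DataFrame(rows, columns=cols)


@dataclass
class QueryPool:
    """Growing set of query homeodomains; provenance records the iteration at
    which each entry was discovered (0 = seed)."""

    entries: dict[str, tuple[str, int]] = field(default_factory=dict)  # id -> (seq, iter)
    _seqs: set[str] = field(default_factory=set)

    @classmethod
    def from_records(cls, records: Iterable[SequenceRecord]) -> "QueryPool":
        pool = cls()
        for rec in records:
            pool.add(rec.id, rec.residues, 0)
        if not pool.entries:
            raise ValueError("seed pool is empty")
        return pool

    def add(self, query_id: str, seq: str, iteration: int) -> bool:
        if seq in self._seqs:
            return False
        base, k = query_id, 1
        while query_id in self.entries:
            query_id = f"{base}.{k}"
            k += 1
        self.entries[query_id] = (seq, iteration)
        self._seqs.add(seq)
        return True

    def items(self):
        return [(qid, seq, it) for qid, (seq, it) in self.entries.items()]


@dataclass
class ScanResult:
    hits: list[HomeodomainHit]
    pool: QueryPool
    iterations: int
    saturated: bool

    @property
    def intact_hits(self) -> list[HomeodomainHit]:
        return [h for h in self.hits if h.intactness == "intact"]


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def recursive_scan(targets: Sequence[SequenceRecord], seed_pool: QueryPool,
                   config: ScanConfig,
                   profiles: Mapping[str, str] | None = None) -> ScanResult:
    """Iterative query-pool search over all six reading frames of the targets.

    Each iteration aligns every pool member against every frame, accepts
    non-overlapping candidates with score >= ``acceptScore`` (greedy by
    descending score; same-frame candidates overlapping an accepted hit by
    more than ``overlapLimit`` aa are treated as the same locus), excises the
    newly accepted domains and adds them to the pool.  Terminates at
    saturation (an iteration accepting no new hit) or ``maxIterations``;
    exhausting the iteration budget flags the result unsaturated rather than
    raising.  Sub-threshold candidates down to the degraded floor are kept and
    reported as degraded remnants.
    """
    if profiles is None:
        from .simulate import default_root_profiles

        profiles = default_root_profiles()
    aligner = make_aligner(config)
    snapper = make_aligner(config)
    snapper.mode = "global"

    frames: list[TranslatedFrame] = []
    for rec in targets:
        if rec.alphabet == "nt":
            frames.extend(translate_six_frames(rec))
        else:
            frames.append(TranslatedFrame(rec.id, "+", 0, rec.residues, 0))
        # protein sources: nt coords absent

    def nt_span(frame_idx: int, aa_start: int, aa_end: int):
        fr = frames[frame_idx]
        if not fr.source_length:
            return None
        return fr.nt_interval(aa_start, aa_end)

    # best candidate per locus; loci on opposite strands/frames of one source
    # that overlap in forward-strand nucleotide space are the same locus (the
    # weaker one is a reading-frame shadow of the stronger)
    loci: list[dict] = []

    def same_locus(a: dict, b: dict) -> bool:
        fa, fb = frames[a["frame_idx"]], frames[b["frame_idx"]]
        if fa.source_id != fb.source_id:
            return False
        if a["frame_idx"] == b["frame_idx"]:
            return _overlap(a["aa_start"], a["aa_end"],
                            b["aa_start"], b["aa_end"]) > config.overlapLimit
        sa, sb = nt_span(a["frame_idx"], a["aa_start"], a["aa_end"]), \
            nt_span(b["frame_idx"], b["aa_start"], b["aa_end"])
        if sa is None or sb is None:
            return False
        return _overlap(sa[0], sa[1], sb[0], sb[1]) > config.overlapLimit

    def merge_candidate(cand: dict) -> None:
        for locus in loci:
            if same_locus(locus, cand):
                if cand["query_id"] == locus.get("pool_qid"):
                    return  # a locus does not support itself
                if cand["score"] > locus["score"]:
                    if locus.get("accepted", False):
                        # boundaries are frozen once excised into the pool;
                        # only the score and best query may improve
                        locus["score"] = cand["score"]
                        locus["query_id"] = cand["query_id"]
                        locus["qseq"] = cand["qseq"]
                        locus["iteration"] = min(locus["iteration"], cand["iteration"])
                    else:
                        locus.update(cand)
                return
        loci.append(cand)

    def _core60(seq: str) -> str:
        # project a 63-aa TALE-frame window into 60-aa space by deleting the
        # canonical loop-extension position; other lengths pass through
        if len(seq) == 63:
            from .simulate import TALE_INSERT_OFFSET as off

            return seq[:off] + seq[off + 3 :]
        return seq

    def snap_boundaries(locus: dict, qseq: str) -> None:
        """Snap a locus window to the best-fitting 60- or 63-aa interval.

        Homeodomain windows are exactly 60 (non-TALE) or 63 (TALE) residues;
        a window inherited from a cross-type query can be off by the 3-aa
        loop extension.  Candidate windows near the current one are compared
        against the discovering query in a common 60-residue space (the
        canonical loop-extension position deleted from 63-aa sequences), so
        the 60-vs-63 decision reflects whether the residues at the insert
        position carry signal rather than a fixed gap-cost asymmetry.
        """
        residues = frames[locus["frame_idx"]].residues
        qcore = _core60(qseq)
        best = None
        for L in (60, 63):
            for start in range(locus["aa_start"] - 3, locus["aa_start"] + 4):
                if start < 0 or start + L > len(residues):
                    continue
                window = residues[start : start + L]
                s = float(snapper.score(_core60(window), qcore))
                key = (s, L == len(qseq), -abs(start - locus["aa_start"]))
                if best is None or key > best[0]:
                    best = (key, start, L)
        if best is not None:
            _, start, L = best
            locus["aa_start"], locus["aa_end"] = start, start + L

    scored: set[str] = set()  # query ids already aligned against all frames
    iterations = 0
    saturated = False
    accepted_keys: set[int] = set()

    while iterations < config.maxIterations:
        iterations += 1
        new_queries = [(qid, seq) for qid, seq, _ in seed_pool.items()
                       if qid not in scored]
        progress = False
        for qid, qseq in new_queries:
            scored.add(qid)
            for fi, fr in enumerate(frames):
                if len(fr.residues) == 0:
                    continue
                # iterate suboptimal non-overlapping alignments by masking
                # each matched interval, so a weaker second domain on the
                # same frame is still seen behind a strong first domain
                work = fr.residues
                for _round in range(4):
                    score = float(aligner.score(work, qseq))
                    if score < config.degradedFloor:
                        break
                    aln = aligner.align(work, qseq)[0]
                    t_blocks, q_blocks = aln.aligned
                    ts, te = int(t_blocks[0][0]), int(t_blocks[-1][1])
                    qs, qe = int(q_blocks[0][0]), int(q_blocks[-1][1])
                    # extend to the full query extent (domains are collinear;
                    # terminal mismatches trimmed by SW are restored here)
                    ext_start = ts - qs
                    ext_end = te + (len(qseq) - qe)
                    clamped = ext_start < 0 or ext_end > len(fr.residues)
                    aa_start = max(ext_start, 0)
                    aa_end = min(ext_end, len(fr.residues))
                    cand = {
                        "frame_idx": fi, "aa_start": aa_start, "aa_end": aa_end,
                        "score": score, "query_id": qid, "clamped": clamped,
                        "iteration": iterations, "qseq": qseq,
                    }
                    merge_candidate(cand)
                    work = work[:ts] + "X" * (te - ts) + work[te:]
        # acceptance pass: greedy by descending score
        order = sorted(range(len(loci)), key=lambda i: (-loci[i]["score"],
                                                        loci[i]["frame_idx"],
                                                        loci[i]["aa_start"]))
        newly_accepted = []
        for i in order:
            c = loci[i]
            if i in accepted_keys or c["score"] < config.acceptScore or c["clamped"]:
                continue
            snap_boundaries(c, c["qseq"])
            c["accepted"] = True
            accepted_keys.add(i)
            newly_accepted.append(i)
            progress = True
        # grow the pool with the excised accepted domains
        for i in newly_accepted:
            c = loci[i]
            fr = frames[c["frame_idx"]]
            seq = fr.residues[c["aa_start"]:c["aa_end"]]
            qid = f"{fr.source_id}|{c['aa_start']}-{c['aa_end']}|{fr.strand}"
            if seed_pool.add(qid, seq, iterations):
                c["pool_qid"] = qid
        if not progress:
            saturated = True
            break

    # harmonize boundaries of accepted loci: processed in descending score,
    # each locus is re-snapped against its best already-fixed neighbour, so
    # members of one family carry mutually consistent window boundaries (a
    # lone ±1 snap error otherwise shifts one row of the later alignment)
    accepted_loci = sorted((loci[i] for i in accepted_keys),
                           key=lambda c: (-c["score"], c["frame_idx"], c["aa_start"]))
    fixed: list[dict] = []
    for locus in accepted_loci:
        window = frames[locus["frame_idx"]].residues[locus["aa_start"]:locus["aa_end"]]
        best_seq, best_score = None, config.acceptScore
        for other in fixed:
            oseq = frames[other["frame_idx"]].residues[other["aa_start"]:other["aa_end"]]
            s = float(snapper.score(_core60(window), _core60(oseq)))
            if s >= best_score:
                best_seq, best_score = oseq, s
        if best_seq is not None:
            snap_boundaries(locus, best_seq)
        fixed.append(locus)

    hits: list[HomeodomainHit] = []
    for c in loci:
        fr = frames[c["frame_idx"]]
        seq = fr.residues[c["aa_start"]:c["aa_end"]]
        if c["clamped"]:
            intact = "truncated"
        elif c["score"] >= config.acceptScore:
            intact = "intact"
        elif c["score"] >= config.degradedFloor:
            intact = "degraded"
        else:
            continue
        if "*" in seq and intact == "intact":
            intact = "degraded"  # in-frame stop: not a functional domain
        try:
            hd_type = classify_tale(seq, profiles, config) if len(seq) >= 50 else "unresolved"
        except ValueError:
            hd_type = "unresolved"
        if fr.source_length:
            nt_start, nt_end = fr.nt_interval(c["aa_start"], c["aa_end"])
        else:
            nt_start = nt_end = None
        hits.append(HomeodomainHit(
            source_id=fr.source_id, strand=fr.strand, frame=fr.frame,
            nt_start=nt_start, nt_end=nt_end,
            aa_start=c["aa_start"], aa_end=c["aa_end"], score=c["score"],
            best_query_id=c["query_id"], hd_type=hd_type, intactness=intact,
            sequence=seq, iteration=c["iteration"],
        ))
    # drop residual reading-frame shadows: a hit overlapping a stronger hit
    # of the same source in forward-nucleotide space, on another strand or
    # frame, is the weaker image of that locus
    spans: dict[str, list[tuple[int, int, str, int, float]]] = {}
    for h in hits:
        if h.nt_start is not None:
            spans.setdefault(h.source_id, []).append(
                (h.nt_start, h.nt_end, h.strand, h.frame, h.score))

    def is_shadow(h: HomeodomainHit) -> bool:
        if h.nt_start is None:
            return False
        for s, e, strand, frame, score in spans.get(h.source_id, []):
            if ((strand, frame) != (h.strand, h.frame) and score > h.score
                    and _overlap(s, e, h.nt_start, h.nt_end) > 0):
                return True
        return False

    hits = [h for h in hits if not is_shadow(h)]
    hits.sort(key=lambda h: (h.source_id, h.strand, h.frame, h.aa_start))
    return ScanResult(hits, seed_pool, iterations, saturated)


# ---------------------------------------------------------------------------
# excision & architecture


def excise_domain(hit: HomeodomainHit, source: SequenceRecord,
                  flank_residues: int = 0) -> tuple[str, bool]:
    """Excise the hit window ± ``flank_residues`` from the translated source.

    Returns ``(peptide, clamped)``; ``clamped`` is set when the window ran
    into a sequence end and was truncated to bounds.
    """
    if hit.aa_end <= hit.aa_start:
        raise ValueError("inverted hit interval")
    if source.alphabet == "nt":
        frames = {(f.strand, f.frame): f for f in translate_six_frames(source)}
        residues = frames[(hit.strand, hit.frame)].residues
    else:
        residues = source.residues
    start = hit.aa_start - flank_residues
    end = hit.aa_end + flank_residues
    clamped = start < 0 or end > len(residues)
    return residues[max(start, 0):min(end, len(residues))], clamped


def detect_architecture(hits: Sequence[HomeodomainHit]) -> str:
    """Call the per-gene domain architecture from that gene's hits.

    two intact -> ``double``; intact + degraded -> ``double_with_degraded``;
    one intact -> ``single``; only truncated -> ``fragment``.
    """
    if not hits:
        raise ValueError("architecture is only called on hit-bearing genes")
    ids = {h.source_id for h in hits}
    if len(ids) != 1:
        raise ValueError(f"hits span multiple sources: {sorted(ids)}")
    n_intact = sum(1 for h in hits if h.intactness == "intact")
    n_degraded = sum(1 for h in hits if h.intactness == "degraded")
    n_trunc = sum(1 for h in hits if h.intactness == "truncated")
    if n_intact >= 2:
        return "double"
    if n_intact == 1 and n_degraded >= 1:
        return "double_with_degraded"
    if n_intact == 1:
        return "single"
    if n_trunc >= 1:
        return "fragment"
    return "fragment"


# ---------------------------------------------------------------------------
# read quantification


@dataclass(frozen=True)
class QuantConfig:
    identityCutoff: float = 0.95
    coverageCutoff: float = 0.90
    libraryTotal: int = 1_000_000
    scalePerMillion: bool = True

    def __post_init__(self):
        if not 0 < self.identityCutoff <= 1:
            raise ConfigError("identityCutoff must be in (0, 1]")
        if self.libraryTotal <= 0:
            raise ConfigError("libraryTotal must be > 0")


def quantify_reads(reads: Sequence[SequenceRecord], transcript: SequenceRecord,
                   config: QuantConfig) -> tuple[int, float]:
    """Count reads matching a transcript at >= 95% identity (inclusive).

    A read counts when its best local alignment to the transcript (either
    strand) covers at least ``coverageCutoff`` of the read at an identity of
    at least ``identityCutoff`` (identical columns / aligned columns).  The
    normalized count is raw / libraryTotal, x1e6 when ``scalePerMillion``.
    """
    if not reads:
        return 0, 0.0
    scan = ScanConfig(gapOpen=5.0, gapExtend=2.0, acceptScore=1.0)
    aligner = make_aligner(scan, alphabet="nt")
    raw = 0
    for read in reads:
        counted = False
        for rseq in (read.residues, revcomp(read.residues)):
            aln = aligner.align(transcript.residues, rseq)[0]
            t_aln, r_aln = str(aln[0]), str(aln[1])
            cols = len(t_aln)  # aligned columns, gap columns included
            if cols == 0:
                continue
            ident = sum(1 for a, b in zip(t_aln, r_aln) if a == b and a != "-")
            aligned_read = sum(1 for b in r_aln if b != "-")
            identity = ident / cols
            coverage = aligned_read / len(read.residues)
            if identity >= config.identityCutoff and coverage >= config.coverageCutoff:
                counted = True
                break
        raw += counted
    norm = raw / config.libraryTotal
    if config.scalePerMillion:
        norm *= 1e6
    return raw, norm
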
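import pytest

from homeoscan.io import SequenceRecord
from homeoscan.search import (ConfigError, HomeodomainHit, QuantConfig, QueryPool,
                              ScanConfig, alignment_score_from_strings,
                              classify_tale, detect_architecture, excise_domain,
                              local_align, make_aligner, quantify_reads,
                              recursive_scan, translate_six_frames)
from homeoscan.simulate import (AMINO_ACIDS, TALE_INSERT_OFFSET,
                                default_root_profiles, revcomp)

from oracles import gotoh_local_score


def _mutate(seq, fraction, rng):
    n = int(round(fraction * len(seq)))
    pos = rng.choice(len(seq), size=n, replace=False)
    out = list(seq)
    for i in pos:
        out[i] = AMINO_ACIDS[(AMINO_ACIDS.index(out[i]) + 1 + int(rng.integers(19))) % 20]
    return "".join(out)


# ---------------------------------------------------------------------------
# translation


def test_single_codon_forward_frame():
    frames = translate_six_frames(SequenceRecord("x", "ATG", "nt"))
    fwd0 = [f for f in frames if f.strand == "+" and f.frame == 0][0]
    assert fwd0.residues == "M"


def test_reverse_complement_frame():
    frames = translate_six_frames(SequenceRecord("x", "CAT", "nt"))
    rev0 = [f for f in frames if f.strand == "-" and f.frame == 0][0]
    assert rev0.residues == "M"


def test_frame_lengths_and_stop_and_ambiguity():
    frames = translate_six_frames(SequenceRecord("x", "ATGTAANATG", "nt"))
    for f in frames:
        assert len(f.residues) == (10 - f.frame) // 3
    fwd0 = [f for f in frames if f.strand == "+" and f.frame == 0][0]
    assert fwd0.residues[1] == "*"       # TAA stop
    assert "X" in fwd0.residues          # NAT ambiguity


def test_translation_contains_planted_domain(dataset):
    truth = dataset.truth_table
    scaffolds = {s.id: s for s in dataset.scaffolds}
    proteins = {p.record.id: p for p in dataset.proteins}
    sample = truth[truth.intact == "intact"].head(10)
    for _, row in sample.iterrows():
        frames = translate_six_frames(scaffolds[row.scaffoldId])
        fr = [f for f in frames if f.strand == row.strand and f.frame == row.frame][0]
        dom = proteins[row.geneId].domains[row.hdIndex]
        domain_aa = proteins[row.geneId].record.residues[dom.aa_start:dom.aa_end]
        assert domain_aa in fr.residues


def test_nucleotide_interval_mapping_roundtrip(dataset):
    truth = dataset.truth_table
    scaffolds = {s.id: s for s in dataset.scaffolds}
    row = truth.iloc[0]
    frames = translate_six_frames(scaffolds[row.scaffoldId])
    fr = [f for f in frames if f.strand == row.strand and f.frame == row.frame][0]
    if row.strand == "+":
        aa_start = (row.hdStartNt - fr.frame) // 3
    else:
        aa_start = (fr.source_length - row.hdEndNt - fr.frame) // 3
    aa_end = aa_start + (row.hdEndNt - row.hdStartNt) // 3
    assert fr.nt_interval(aa_start, aa_end) == (row.hdStartNt, row.hdEndNt)


# ---------------------------------------------------------------------------
# local alignment


def test_self_alignment_score_is_diagonal_sum():
    from Bio.Align import substitution_matrices

    matrix = substitution_matrices.load("BLOSUM62")
    seq = default_root_profiles()["nonTALE"]
    aln = local_align(seq, seq, ScanConfig())
    assert aln.score == sum(matrix[a, a] for a in seq)
    assert (aln.target_start, aln.target_end) == (0, len(seq))


def test_alignment_score_self_consistent(rng):
    cfg = ScanConfig()
    for _ in range(20):
        a = "".join(rng.choice(list(AMINO_ACIDS), size=40))
        b = _mutate(a, 0.3, rng)
        aln = local_align(a, b, cfg)
        recomputed = alignment_score_from_strings(aln.aligned_query,
                                                  aln.aligned_target, cfg)
        assert recomputed == pytest.approx(aln.score)


def test_local_align_matches_independent_dp_oracle(rng):
    """Production Smith-Waterman equals a hand-rolled Gotoh DP on random pairs."""
    cfg = ScanConfig()
    for _ in range(200):
        a = "".join(rng.choice(list(AMINO_ACIDS), size=30))
        b = "".join(rng.choice(list(AMINO_ACIDS), size=30))
        assert local_align(a, b, cfg).score == pytest.approx(
            gotoh_local_score(a, b, cfg.gapOpen, cfg.gapExtend))


def test_unknown_matrix_is_config_error():
    with pytest.raises(ConfigError):
        make_aligner(ScanConfig(scoringMatrix="NOSUCH62"))


# ---------------------------------------------------------------------------
# TALE typing


def test_classify_profiles_and_constructed_insert():
    profiles = default_root_profiles()
    assert classify_tale(profiles["nonTALE"], profiles) == "nonTALE"
    assert classify_tale(profiles["TALE"], profiles) == "TALE"
    constructed = (profiles["nonTALE"][:TALE_INSERT_OFFSET] + "QRS"
                   + profiles["nonTALE"][TALE_INSERT_OFFSET:])
    assert classify_tale(constructed, profiles) == "TALE"


def test_classify_short_candidate_rejected():
    with pytest.raises(ValueError):
        classify_tale("M" * 49, default_root_profiles())


# ---------------------------------------------------------------------------
# excision


def _hit(aa_start, aa_end, source_len=200):
    return HomeodomainHit("src", "+", 0, None, None, aa_start, aa_end, 200.0,
                          "q", "nonTALE", "intact", "X" * (aa_end - aa_start), 1)


def test_excise_flank_window_and_clamp():
    protein = SequenceRecord("src", "".join(AMINO_ACIDS[i % 20] for i in range(200)))
    pep, clamped = excise_domain(_hit(100, 160), protein, 0)
    assert pep == protein.residues[100:160] and not clamped
    pep, clamped = excise_domain(_hit(100, 160), protein, 5)
    assert pep == protein.residues[95:165] and len(pep) == 70 and not clamped
    pep, clamped = excise_domain(_hit(2, 62), protein, 5)
    assert pep == protein.residues[0:67] and clamped


def test_excise_inverted_interval_rejected():
    protein = SequenceRecord("src", "M" * 50)
    with pytest.raises(ValueError):
        excise_domain(_hit(30, 30), protein, 0)


# ---------------------------------------------------------------------------
# recursive scan


def test_empty_target_set_saturates_immediately():
    profiles = default_root_profiles()
    pool = QueryPool.from_records([SequenceRecord("seed", profiles["nonTALE"])])
    result = recursive_scan([], pool, ScanConfig())
    assert result.hits == [] and result.iterations == 1 and result.saturated


def test_chain_discovery_requires_second_iteration(rng):
    """A domain out of the seed's reach is found through an intermediate."""
    profiles = default_root_profiles()
    seed = profiles["nonTALE"]
    cfg = ScanConfig(acceptScore=150.0)
    near = _mutate(seed, 0.35, rng)
    distant = _mutate(near, 0.35, rng)
    # verify the chain premise before the behavioural assertion
    s_seed_near = local_align(seed, near, cfg).score
    s_seed_distant = local_align(seed, distant, cfg).score
    s_near_distant = local_align(near, distant, cfg).score
    assert s_seed_near >= cfg.acceptScore > s_seed_distant
    assert s_near_distant >= cfg.acceptScore
    flank = "".join(rng.choice(list(AMINO_ACIDS), size=20))
    targets = [SequenceRecord("near", flank + near + flank),
               SequenceRecord("distant", flank + distant + flank)]
    pool = QueryPool.from_records([SequenceRecord("seed", seed)])
    result = recursive_scan(targets, pool, cfg, profiles=profiles)
    by_src = {h.source_id: h for h in result.hits if h.intactness == "intact"}
    assert set(by_src) == {"near", "distant"}
    assert by_src["near"].iteration == 1
    assert by_src["distant"].iteration == 2
    assert result.saturated


def test_scan_deterministic_across_runs(dataset):
    profiles = dataset.root_profiles
    cfg = ScanConfig()
    subset = dataset.scaffolds[:10]
    runs = []
    for _ in range(2):
        seeds = [SequenceRecord(f"seed|{k}", v) for k, v in sorted(profiles.items())]
        result = recursive_scan(subset, QueryPool.from_records(seeds), cfg,
                                profiles=profiles)
        runs.append([(h.source_id, h.strand, h.frame, h.aa_start, h.aa_end,
                      h.score, h.intactness) for h in result.hits])
    assert runs[0] == runs[1]


def test_intact_hits_rescore_above_accept_threshold(scan_result):
    """Every reported intact hit re-aligns to its best query at >= acceptScore."""
    cfg = ScanConfig()
    pool = {qid: seq for qid, seq, _ in scan_result.pool.items()}
    profiles = default_root_profiles()
    pool.update({f"seed|{k}": v for k, v in profiles.items()})
    checked = 0
    for h in scan_result.intact_hits[:30]:
        q = pool[h.best_query_id]
        assert local_align(q, h.sequence, cfg).score >= cfg.acceptScore * 0.95
        checked += 1
    assert checked > 0


def test_unsaturated_scan_is_flagged_not_raised(dataset):
    profiles = dataset.root_profiles
    seeds = [SequenceRecord(f"seed|{k}", v) for k, v in sorted(profiles.items())]
    result = recursive_scan(dataset.scaffolds[:6], QueryPool.from_records(seeds),
                            ScanConfig(maxIterations=1), profiles=profiles)
    assert not result.saturated


# ---------------------------------------------------------------------------
# architecture


def test_architecture_mapping():
    intact = _hit(10, 70)
    second = HomeodomainHit("src", "+", 0, None, None, 90, 150, 220.0, "q",
                            "nonTALE", "intact", "X" * 60, 1)
    degraded = HomeodomainHit("src", "+", 0, None, None, 90, 150, 80.0, "q",
                              "nonTALE", "degraded", "X" * 60, 1)
    truncated = HomeodomainHit("src", "+", 0, None, None, 0, 40, 90.0, "q",
                               "unresolved", "truncated", "X" * 40, 1)
    assert detect_architecture([intact]) == "single"
    assert detect_architecture([intact, second]) == "double"
    assert detect_architecture([intact, degraded]) == "double_with_degraded"
    assert detect_architecture([truncated]) == "fragment"
    with pytest.raises(ValueError):
        detect_architecture([])


def test_architecture_calls_against_simulator_truth(dataset, scan_result):
    """Spot-check: a double family and a degraded family call correctly."""
    from homeoscan.pipeline import evaluate_architecture

    result = evaluate_architecture(dataset.truth_table, scan_result.hits)
    assert result["accuracy"] >= 0.95


# ---------------------------------------------------------------------------
# read quantification


def test_quantify_no_reads():
    transcript = SequenceRecord("t", "ACGT" * 100, "nt")
    assert quantify_reads([], transcript, QuantConfig()) == (0, 0.0)


def test_quantify_counts_matching_reads(rng):
    nt = "ACGT"
    transcript_seq = "".join(nt[i] for i in rng.integers(4, size=600))
    transcript = SequenceRecord("t", transcript_seq, "nt")
    reads = []
    for k in range(3):  # copies with <=4 mismatches: identity >= 96%
        start = 50 + 120 * k
        read = list(transcript_seq[start:start + 100])
        for pos in (10, 40, 70):
            read[pos] = nt[(nt.index(read[pos]) + 1) % 4]
        reads.append(SequenceRecord(f"match{k}", "".join(read), "nt"))
    for k in range(2):
        reads.append(SequenceRecord(
            f"rand{k}", "".join(nt[i] for i in rng.integers(4, size=100)), "nt"))
    config = QuantConfig(libraryTotal=1_000_000)
    raw, norm = quantify_reads(reads, transcript, config)
    assert raw == 3
    assert norm == pytest.approx(3.0)  # per million


def test_exact_95_percent_identity_is_inclusive(rng):
    nt = "ACGT"
    transcript_seq = "".join(nt[i] for i in rng.integers(4, size=400))
    transcript = SequenceRecord("t", transcript_seq, "nt")
    read = list(transcript_seq[100:200])
    for pos in range(5, 100, 20):  # 5 evenly spread mismatches -> 95.0%
        read[pos] = nt[(nt.index(read[pos]) + 1) % 4]
    raw, _ = quantify_reads([SequenceRecord("r", "".join(read), "nt")],
                            transcript, QuantConfig())
    assert raw == 1


def test_reverse_strand_read_counts(rng):
    nt = "ACGT"
    transcript_seq = "".join(nt[i] for i in rng.integers(4, size=400))
    transcript = SequenceRecord("t", transcript_seq, "nt")
    read = SequenceRecord("r", revcomp(transcript_seq[120:220]), "nt")
    raw, _ = quantify_reads([read], transcript, QuantConfig())
    assert raw == 1
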
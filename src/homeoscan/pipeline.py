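"""End-to-end orchestration: simulate -> scan -> align -> tree -> supports ->
clades -> gain/loss, with a reproducible run manifest.

Between domain excision and tree building the original analyses used an
external aligner plus manual editing; here the excised homeodomains are
indel-free 60/63-aa windows by construction, so they stack into the shared
63-column frame directly (non-TALE windows receive gaps at the canonical
loop-extension columns).  Real data would re-enter the pipeline at this
point as an aligned FASTA.

Every stochastic stage derives its seed from the single global seed and the
stage name, so two runs with the same configuration are byte-identical; the
manifest records output checksums to prove it.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .clades import CladeCall, CladeCriteria, CladeRegistry, call_clades, reconcile_registry
from .dollo import dollo_events
from .io import SequenceRecord, write_fasta, write_tsv, write_newick
from .njtree import (Alignment, BootstrapConfig, aa_distance, annotate_bootstrap,
                     bootstrap_support, neighbor_joining, root_with_outgroup)
from .reconcile import AnnotatedTree, transfer_support, write_annotated_newick
from .search import (HomeodomainHit, QueryPool, ScanConfig, ScanResult,
                     detect_architecture, hits_to_frame, recursive_scan)
from .simulate import (SimulationConfig, SimulatedDataset, TALE_INSERT_OFFSET,
                       simulate_dataset, write_dataset)

STAGES = ("simulate", "scan", "align", "buildtree", "reconcile", "callclades",
          "gainloss")


def stage_seed(global_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(digest, 16) % (2**31)


@dataclass
class PipelineConfig:
    outdir: str | Path = "homeoscan_run"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    bootstrap: BootstrapConfig = field(default_factory=lambda: BootstrapConfig(200))
    criteria: CladeCriteria = field(default_factory=CladeCriteria)
    distance_model: str = "p"
    #: maximum within-clade p-distance for a call to count as one family when
    #: condensing nested calls into a disjoint family partition
    condensation_max_distance: float = 0.45
    stages: Sequence[str] = STAGES


@dataclass
class RunResult:
    config: PipelineConfig
    dataset: SimulatedDataset | None = None
    scan_result: ScanResult | None = None
    alignment: Alignment | None = None
    tree: dendropy.Tree | None = None
    supports: dict | None = None
    annotated: AnnotatedTree | None = None
    calls: list[CladeCall] = field(default_factory=list)
    registry: CladeRegistry | None = None
    events: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def align_hits(hits: Sequence[HomeodomainHit]) -> Alignment:
    """Stack one intact homeodomain per gene into the 63-column frame.

    The N-terminal-most intact hit represents each gene (the convention for
    two-domain genes); 60-aa windows receive gaps at the loop-extension
    columns.  Hits with other lengths are skipped.
    """
    per_gene: dict[str, HomeodomainHit] = {}
    for h in hits:
        if h.intactness != "intact" or h.aa_length not in (60, 63):
            continue
        prev = per_gene.get(h.source_id)
        if prev is None or h.aa_start < prev.aa_start:
            per_gene[h.source_id] = h
    ids, rows = [], []
    for gid in sorted(per_gene):
        h = per_gene[gid]
        row = h.sequence
        if len(row) == 60:
            row = row[:TALE_INSERT_OFFSET] + "---" + row[TALE_INSERT_OFFSET:]
        ids.append(gid)
        rows.append(row)
    return Alignment(ids, rows)


def condense_to_families(calls: Sequence[CladeCall], alignment: Alignment,
                         max_distance: float) -> list[CladeCall]:
    """Select a disjoint set of cohesive calls as the family partition.

    A call qualifies when its maximum within-member p-distance is below
    ``max_distance`` (members of one family stay mutually similar; unions of
    families do not).  Among qualifying calls, larger ones win; overlapping
    smaller calls are dropped.
    """
    dm = aa_distance(alignment, "p")
    index = {i: k for k, i in enumerate(dm.ids)}
    chosen: list[CladeCall] = []
    used: set[str] = set()
    for call in sorted(calls, key=lambda c: (-len(c.members), c.members)):
        members = [m for m in call.members if m in index]
        if len(members) < 2 or used.intersection(members):
            continue
        idx = [index[m] for m in members]
        if dm.matrix[np.ix_(idx, idx)].max() >= max_distance:
            continue
        chosen.append(call)
        used.update(members)
    return sorted(chosen, key=lambda c: c.members)


def run_pipeline(config: PipelineConfig,
                 ml_tree: dendropy.Tree | None = None,
                 bayes_tree: dendropy.Tree | None = None) -> RunResult:
    """Execute the requested stages in order, writing each stage's outputs
    before the next starts.  Failures abort with the failing stage named."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = RunResult(config)
    manifest: dict = {
        "config": {
            "seed": config.seed,
            "simulation": asdict(config.simulation),
            "scan": asdict(config.scan),
            "bootstrap": asdict(config.bootstrap),
            "distance_model": config.distance_model,
            "condensation_max_distance": config.condensation_max_distance,
            "stages": list(config.stages),
        },
        "versions": _versions(),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }
    outputs: dict[str, Path] = {}

    def record(stage: str, paths: Mapping[str, Path]) -> None:
        manifest["stages"][stage] = {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in sorted(paths.items())
        }
        outputs.update(paths)

    try:
        for stage in config.stages:
            if stage == "simulate":
                sim = SimulationConfig(**{**asdict(config.simulation),
                                          "seed": stage_seed(config.seed, "simulate")})
                result.dataset = simulate_dataset(sim)
                paths = write_dataset(result.dataset, outdir / "simulated")
                record(stage, {k: Path(v) for k, v in paths.items()})
            elif stage == "scan":
                ds = result.dataset
                if ds is None:
                    raise RuntimeError("scan stage requires simulated (or loaded) scaffolds")
                profiles = ds.root_profiles
                seeds = [SequenceRecord(f"seed|{k}", v) for k, v in sorted(profiles.items())]
                result.scan_result = recursive_scan(
                    ds.scaffolds, QueryPool.from_records(seeds), config.scan,
                    profiles=profiles)
                hits_path = outdir / "hits.tsv"
                write_tsv(hits_to_frame(result.scan_result.hits), hits_path,
                          comment="homeodomain hits (nt coords 0-based half-open, forward strand)")
                pool_path = outdir / "query_pool.fasta"
                write_fasta([SequenceRecord(qid, seq) for qid, seq, _ in
                             result.scan_result.pool.items()], pool_path)
                dom_path = outdir / "domains.fasta"
                write_fasta([SequenceRecord(
                    f"{h.source_id}|{h.aa_start}-{h.aa_end}|{h.strand}|{h.hd_type}",
                    h.sequence) for h in result.scan_result.intact_hits], dom_path)
                record(stage, {"hits": hits_path, "pool": pool_path, "domains": dom_path})
            elif stage == "align":
                aln = align_hits(result.scan_result.hits)
                og = result.dataset.outgroup
                og_row = og.residues[:TALE_INSERT_OFFSET] + "---" + og.residues[TALE_INSERT_OFFSET:]
                aln = Alignment(aln.ids + [og.id], aln.rows + [og_row])
                result.alignment = aln
                path = outdir / "domain_alignment.fasta"
                write_fasta([SequenceRecord(i, r) for i, r in zip(aln.ids, aln.rows)], path)
                record(stage, {"alignment": path})
            elif stage == "buildtree":
                aln = result.alignment
                dm = aa_distance(aln, config.distance_model)
                tree = neighbor_joining(dm)
                counts = bootstrap_support(
                    aln, config.distance_model,
                    BootstrapConfig(config.bootstrap.replicates,
                                    stage_seed(config.seed, "buildtree")))
                result.supports = counts
                result.tree = root_with_outgroup(tree, result.dataset.outgroup.id)
                # annotate after rooting: node labels belong to bipartitions,
                # and rerooting reshuffles the node-edge correspondence
                annotate_bootstrap(result.tree, counts)
                tree_path = outdir / "nj_tree.nwk"
                write_newick(result.tree, tree_path)
                support_rows = pd.DataFrame(
                    [{"bipartition": ";".join(sorted(k)), "count": v}
                     for k, v in sorted(counts.items(),
                                        key=lambda kv: (-kv[1], sorted(kv[0])))])
                support_path = outdir / "bootstrap_bipartitions.tsv"
                write_tsv(support_rows, support_path,
                          comment=f"bootstrap counts out of {config.bootstrap.replicates}")
                record(stage, {"tree": tree_path, "supports": support_path})
            elif stage == "reconcile":
                result.annotated = transfer_support(
                    result.tree, nj=result.tree, ml=ml_tree, bayes=bayes_tree,
                    nj_replicates=config.bootstrap.replicates)
                path = outdir / "annotated_tree.nwk"
                write_annotated_newick(result.annotated, path)
                record(stage, {"annotated": path})
            elif stage == "callclades":
                calls = call_clades(result.annotated, config.criteria)
                og_id = result.dataset.outgroup.id
                calls = [c for c in calls if og_id not in c.members]
                result.calls = calls
                families = condense_to_families(calls, result.alignment,
                                                config.condensation_max_distance)
                registry, report = reconcile_registry(
                    families, CladeRegistry.empty(), prefix="FAM")
                result.registry = registry
                calls_path = outdir / "clade_calls.tsv"
                write_tsv(pd.DataFrame(
                    [{"node": c.node_id, "justification": c.justification,
                      "nMembers": len(c.members),
                      "supports": json.dumps({k: v for k, v in c.supports.items()}),
                      "members": ",".join(c.members)} for c in calls]),
                    calls_path, comment="called clades (nested calls allowed)")
                reg_path = outdir / "registry.tsv"
                registry.to_tsv(reg_path, comment="condensed family registry")
                rep_path = outdir / "revision_report.tsv"
                report.to_tsv(rep_path)
                record(stage, {"calls": calls_path, "registry": reg_path,
                               "report": rep_path})
            elif stage == "gainloss":
                reg = result.registry.frame
                if len(reg):
                    presence = pd.crosstab(reg["clade"], reg["species"]).astype(bool)
                    species = [lf.taxon.label for lf in
                               dendropy.Tree.get(data=config.simulation.speciesTree,
                                                 schema="newick").leaf_node_iter()]
                    for sp in species:
                        if sp not in presence.columns:
                            presence[sp] = False
                    presence = presence[species]
                    events, summary = dollo_events(presence, config.simulation.speciesTree)
                    result.events = events
                else:
                    events, summary = [], pd.DataFrame(
                        columns=["edge", "event", "count", "families"])
                ev_path = outdir / "gain_loss_events.tsv"
                write_tsv(pd.DataFrame(
                    [{"family": e.family_id, "edge": e.edge, "event": e.event}
                     for e in events]), ev_path, comment="Dollo gain/loss events")
                sum_path = outdir / "gain_loss_summary.tsv"
                write_tsv(summary, sum_path)
                record(stage, {"events": ev_path, "summary": sum_path})
            else:
                raise ValueError(f"unknown stage {stage!r}")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    result.manifest = manifest
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return result


def _versions() -> dict:
    import Bio
    import dendropy as _dendropy

    from . import __version__

    return {"homeoscan": __version__, "numpy": np.__version__,
            "pandas": pd.__version__, "biopython": Bio.__version__,
            "dendropy": _dendropy.__version__}


def manifest_checksums(manifest: dict) -> dict:
    """The determinism-relevant part of a manifest (checksums only)."""
    return {stage: {name: info["sha256"] for name, info in files.items()}
            for stage, files in manifest["stages"].items()}


# ---------------------------------------------------------------------------
# evaluation against simulator truth


def match_hits_to_truth(truth_table: pd.DataFrame,
                        hits: Sequence[HomeodomainHit],
                        tol_nt: int = 6) -> dict[int, HomeodomainHit | None]:
    """Match each truth row to a same-strand hit within ``tol_nt`` of both
    nucleotide boundaries (±2 codons)."""
    by_source: dict[str, list[HomeodomainHit]] = {}
    for h in hits:
        by_source.setdefault(h.source_id, []).append(h)
    matches: dict[int, HomeodomainHit | None] = {}
    for idx, row in truth_table.iterrows():
        found = None
        for h in by_source.get(row.scaffoldId, []):
            if (h.strand == row.strand and h.nt_start is not None
                    and abs(h.nt_start - row.hdStartNt) <= tol_nt
                    and abs(h.nt_end - row.hdEndNt) <= tol_nt):
                found = h
                break
        matches[idx] = found
    return matches


def evaluate_hits(truth_table: pd.DataFrame, hits: Sequence[HomeodomainHit],
                  accept_score: float, tol_nt: int = 6) -> dict:
    """Recovery and precision of the scan against the planted truth."""
    matches = match_hits_to_truth(truth_table, hits, tol_nt)
    intact_rows = truth_table[truth_table.intact == "intact"]
    n_intact = len(intact_rows)
    recovered = sum(1 for idx in intact_rows.index
                    if matches[idx] is not None and matches[idx].intactness == "intact")
    degraded_rows = truth_table[truth_table.intact == "degraded"]
    deg_recovered = sum(1 for idx in degraded_rows.index
                        if matches[idx] is not None
                        and matches[idx].intactness == "degraded")
    matched_ids = {id(h) for h in matches.values() if h is not None}
    # precision over intact-called hits: none may fall outside planted loci
    loose = match_hits_to_truth(truth_table, hits, tol_nt=90)
    loose_ids = {id(h) for h in loose.values() if h is not None}
    false_intact = [h for h in hits
                    if h.intactness == "intact" and id(h) not in matched_ids
                    and id(h) not in loose_ids]
    n_intact_hits = sum(1 for h in hits if h.intactness == "intact")
    return {
        "n_planted_intact": n_intact,
        "intact_recovered": recovered,
        "intact_recovery": recovered / n_intact if n_intact else 1.0,
        "n_planted_degraded": len(degraded_rows),
        "degraded_recovered": deg_recovered,
        "intact_precision": (1.0 if not n_intact_hits
                             else 1.0 - len(false_intact) / n_intact_hits),
    }


def truth_architecture(truth_table: pd.DataFrame) -> dict[str, str]:
    out: dict[str, str] = {}
    for gene, grp in truth_table.groupby("geneId"):
        if len(grp) == 1:
            out[gene] = "single"
        elif (grp.intact == "degraded").any():
            out[gene] = "double_with_degraded"
        else:
            out[gene] = "double"
    return out


def evaluate_architecture(truth_table: pd.DataFrame,
                          hits: Sequence[HomeodomainHit]) -> dict:
    """Per-gene architecture calls compared with the planted truth."""
    truth = truth_architecture(truth_table)
    by_gene: dict[str, list[HomeodomainHit]] = {}
    for h in hits:
        by_gene.setdefault(h.source_id, []).append(h)
    n_ok = 0
    mismatches = []
    for gene, expected in truth.items():
        gene_hits = by_gene.get(gene, [])
        call = detect_architecture(gene_hits) if gene_hits else "none"
        if call == expected:
            n_ok += 1
        else:
            mismatches.append((gene, call, expected))
    return {"n_genes": len(truth), "n_match": n_ok,
            "accuracy": n_ok / len(truth) if truth else 1.0,
            "mismatches": mismatches}


def evaluate_clades(calls: Sequence[CladeCall], dataset: SimulatedDataset) -> dict:
    """Fraction of multi-member planted families recovered with exactly their
    member set by some clade call (single-member families cannot form an
    internal node and are reported separately)."""
    call_sets = {frozenset(c.members) for c in calls}
    recovered = 0
    n_multi = 0
    n_single = 0
    missed = []
    for fam in dataset.families:
        members = frozenset(g for _, g in fam.member_genes)
        if len(members) < 2:
            n_single += 1
            continue
        n_multi += 1
        if members in call_sets:
            recovered += 1
        else:
            missed.append(fam.family_id)
    return {"n_families_multi": n_multi, "n_recovered": recovered,
            "recovery": recovered / n_multi if n_multi else 1.0,
            "n_single_member": n_single, "missed": missed}
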
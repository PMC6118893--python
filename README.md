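# homeoscan

Homeobox genes are transcription-factor genes defined by the homeodomain, a
~60-amino-acid helix-turn-helix DNA-binding domain (63 aa in the TALE class,
which carries a Three-Amino-acid Loop Extension between helices 1 and 2).
Spiralian genomes harbour large, fast-evolving radiations of
difficult-to-classify TALE- and PRD-class homeobox genes whose orthology is
cryptic: finding them requires iterative homology searches run to
saturation, and naming them requires reconciling tree-based clade calls with
prior nomenclature systems. `homeoscan` implements that survey pipeline as a
reusable, tested Python library for people who annotate and classify
homeobox (or other domain-defined) gene families in new genomes and
transcriptomes:

* **Recursive homeodomain search** — exact Smith-Waterman over all six
  reading frames, excising each accepted domain into the query pool and
  iterating until saturation; hits are typed TALE/non-TALE, flagged
  intact/degraded/truncated, and per-gene architectures (single, double,
  double-with-degraded, fragment) are called.
* **Tree building** — p or Poisson amino-acid distances with pairwise
  deletion, Saitou-Nei neighbor joining with deterministic tie-breaking,
  column bootstrap, outgroup rooting.
* **Support reconciliation** — mapping NJ bootstrap counts, ML bootstrap
  percentages and Bayesian posteriors from separate trees onto equivalent
  nodes of a target tree via unrooted-bipartition identity, with explicit
  `-` marks where a node has no equivalent; the `nj|ml|pp` label dialect
  round-trips through Newick.
* **Clade calling and nomenclature** — a node is a clade if any support
  exceeds 70%, if it appears in all three analyses, or on structural
  evidence; calls are reconciled against a prior registry by membership
  overlap (additions, reclassifications, newly erected Roman-numeral
  clades) and same-species paralogues receive stable letters.
* **Gain/loss reconstruction** — minimum single-gain (Dollo) events per
  family on a species cladogram, with any-gain/all-loss collapsing of
  multi-species groups.
* **Conservation analyses** — identity masking against a reference row,
  unique-variant column detection, and log-odds motif scanning.
* **Synthetic data with ground truth** — gene families evolved by
  birth-death on a species tree, 60/63-aa domains embedded in nucleotide
  scaffolds on both strands, two-domain and degraded-domain architectures,
  conserved C-terminal motifs, and exact truth tables, so every stage is
  testable without downloads.

## Worked example

```python
from homeoscan import (SimulationConfig, simulate_dataset, ScanConfig,
                       QueryPool, recursive_scan, SequenceRecord,
                       default_root_profiles)

ds = simulate_dataset(SimulationConfig(seed=1))
profiles = default_root_profiles()
seeds = [SequenceRecord(f"seed|{k}", v) for k, v in sorted(profiles.items())]
result = recursive_scan(ds.scaffolds, QueryPool.from_records(seeds), ScanConfig())
print(len(ds.scaffolds), "scaffolds;", len(result.intact_hits),
      "intact homeodomains in", result.iterations, "iterations;",
      "saturated:", result.saturated)
hit = result.intact_hits[0]
print(hit.source_id, hit.strand, hit.nt_start, hit.nt_end, hit.hd_type,
      round(hit.score))
```

prints

```
83 scaffolds; 112 intact homeodomains in 6 iterations; saturated: True
Cgig|fam000|g0 + 114 294 nonTALE 264
```

— 83 simulated genes yielding 112 intact-scored homeodomain windows (this
dataset plants 109 intact domains, all recovered at exact coordinates, plus
three borderline degraded remnants that cross the intact threshold; see the
methods note on that twilight zone). The first hit sits at forward-strand
nucleotides 114–294 (a 60-aa non-TALE domain, 180 nt) with Smith-Waterman
score 264 against its best pool query. The whole pipeline
(simulate → scan → align → tree → supports → clades → gain/loss) runs as

```bash
homeoscan run --outdir run1 --seed 1 --high-signal
```

and writes per-stage outputs plus a `manifest.json` of checksums; a second
run with the same seed is byte-identical. The registry arithmetic on the
shipped TALE revision table is available as

```python
from homeoscan import load_revision_table, revision_inputs, reconcile_registry
prior, calls = revision_inputs(load_revision_table())
registry, report = reconcile_registry(calls, prior)
print(report.n_new_clades, report.n_clades_with_additions,
      report.n_clades_losing_members)   # -> 10 5 2
```

ten newly erected TALE clades, five prior clades with new orthologues, two
prior clades losing reclassified members.

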
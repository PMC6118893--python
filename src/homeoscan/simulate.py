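"""Synthetic homeobox-gene data with known ground truth.

Gene families are evolved on a fixed species tree under a linear birth-death
process (duplication = bifurcation within a species-tree edge, loss = lineage
pruning).  Each family carries a homeodomain of 60 amino acids, or 63 for
TALE-class families, which have a three-residue loop extension between helices
1 and 2; a configurable fraction of TALE families carry a second homeodomain,
optionally degraded beyond alignability.  Proteins are reverse-translated and
embedded in random nucleotide scaffolds, half of them on the reverse strand,
with exact 0-based half-open coordinates recorded in a truth table.

Sequence evolution is deliberately simple: independent-site Poisson
substitution where each event replaces the residue with one drawn from a
uniform stationary distribution over the other 19 amino acids.  There is no
rate heterogeneity and no indel process outside the fixed 3-aa insert, so true
alignments are column-exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .io import SequenceRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_IDX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: 60-aa homeodomain consensus used as the non-TALE ancestral profile.
HD60_CONSENSUS = "RKRGRQTYTRYQTLELEKEFHFNRYLTRRRRIEIAHALCLTERQIKIWFQNRRMKWKKEN"
assert len(HD60_CONSENSUS) == 60

#: Offset in the 60-aa frame after which the TALE loop extension is inserted
#: (between positions 24 and 25, the loop between helices 1 and 2).
TALE_INSERT_OFFSET = 25
#: The three inserted residues of the ancestral TALE profile.
TALE_INSERT = "PYP"
#: Columns occupied by the insert in the shared 63-column alignment frame.
TALE_INSERT_COLUMNS = (25, 26, 27)

#: Conserved C-terminal motif planted downstream of the homeodomain in motif
#: bearing families (a stand-in for clade-restricted motifs such as PADRE).
MOTIF_CONSENSUS = "WFGNPEDRAYKL"

#: Default species tree: four annelids, one brachiopod, three molluscs.
DEFAULT_SPECIES_TREE = (
    "(((Slam:0.10,Pdum:0.10):0.08,(Ctel:0.12,Hrob:0.14):0.06):0.10,"
    "((Cgig:0.12,Lgig:0.10):0.06,Lana:0.16):0.08);"
)


def default_root_profiles() -> dict[str, str]:
    """Ancestral homeodomain profiles: one 60-aa (non-TALE), one 63-aa (TALE)."""
    hd63 = HD60_CONSENSUS[:TALE_INSERT_OFFSET] + TALE_INSERT + HD60_CONSENSUS[TALE_INSERT_OFFSET:]
    return {"nonTALE": HD60_CONSENSUS, "TALE": hd63}


class ConfigError(ValueError):
    pass


def high_signal_config(**overrides) -> "SimulationConfig":
    """Study conditions for end-to-end family-recovery experiments.

    Lower within-family divergence and more distinct family profiles than the
    default: family clades then carry decisive bootstrap support, which is
    what the clade-recovery claim is conditioned on.  The default
    (moderate-divergence) configuration remains the reference for search
    sensitivity and architecture calling.
    """
    params = dict(substitutionRate=0.4, familyStepLength=0.25)
    params.update(overrides)
    return SimulationConfig(**params)


@dataclass
class SimulationConfig:
    """Parameters of the generator.

    Rates are per gene (or per site) per unit of species-tree branch length.
    ``familyStepLength`` controls how far successive family root profiles
    diverge from one another along a chain started at the class consensus;
    moderate steps keep neighbouring families within recursive-search reach
    while leaving families mutually distinguishable.
    """

    speciesTree: str = DEFAULT_SPECIES_TREE
    duplicationRate: float = 0.3
    lossRate: float = 0.2
    substitutionRate: float = 0.55
    nFamilies: int = 12
    taleFraction: float = 0.4
    doubleHdFraction: float = 0.5
    degradeFraction: float = 0.5
    motifFraction: float = 0.5
    familyStepLength: float = 0.2
    scaffoldFlankLength: int = 90
    seed: int = 0

    #: Extra substitution-rate multiplier applied to degraded second domains.
    degradeRateMultiplier: float = 5.0
    #: Fraction of degraded-domain positions replaced uniformly at random.
    degradeScrambleFraction: float = 0.10

    def validate(self) -> None:
        for name in ("duplicationRate", "lossRate", "substitutionRate",
                     "familyStepLength", "degradeRateMultiplier"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("taleFraction", "doubleHdFraction", "degradeFraction",
                     "motifFraction", "degradeScrambleFraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.nFamilies < 1:
            raise ConfigError("nFamilies must be >= 1")
        if self.scaffoldFlankLength < 0:
            raise ConfigError("scaffoldFlankLength must be >= 0")


# ---------------------------------------------------------------------------
# gene trees


class GeneNode:
    """Minimal mutable gene-tree node (branch lengths in species-tree units)."""

    __slots__ = ("children", "length", "name", "species")

    def __init__(self, length: float = 0.0, name: str | None = None, species: str | None = None):
        self.children: list[GeneNode] = []
        self.length = float(length)
        self.name = name
        self.species = species

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["GeneNode"]:
        if self.is_leaf():
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def to_newick(self) -> str:
        def fmt(n: GeneNode) -> str:
            if n.is_leaf():
                return f"{n.name}:{n.length:.6f}"
            inner = ",".join(fmt(c) for c in n.children)
            return f"({inner}):{n.length:.6f}"

        return fmt(self)[: -len(f":{self.length:.6f}")] + ";"


@dataclass
class FamilyTruth:
    """Ground truth for one simulated gene family."""

    family_id: str
    gene_tree: str                      # Newick, present only if >=1 survivor
    member_genes: list[tuple[str, str]]  # (species, gene_id)
    presence_row: dict[str, bool]
    hd_type: str = "nonTALE"            # "TALE" or "nonTALE"
    double_hd: bool = False
    degraded_second: bool = False
    has_motif: bool = False
    root: GeneNode | None = None        # in-memory tree (not serialized)


def _parse_species_tree(newick: str):
    from .io import read_newick, FormatError

    tree = read_newick(newick, rooting="force-rooted")
    if tree.seed_node.num_child_nodes() == 0:
        raise FormatError("species tree has no branching structure")
    return tree


def _birth_death_edge(lineage: GeneNode, t: float, d: float, l: float,
                      rng: np.random.Generator) -> list[GeneNode]:
    """Evolve one gene lineage along a species-tree edge of length ``t``.

    Returns the lineages surviving to the bottom of the edge; duplications
    bifurcate the gene tree in place, losses terminate lineages.
    """
    total = d + l
    if total == 0.0 or t <= 0.0:
        lineage.length += max(t, 0.0)
        return [lineage]
    wait = rng.exponential(1.0 / total)
    if wait >= t:
        lineage.length += t
        return [lineage]
    lineage.length += wait
    if rng.random() < d / total:  # duplication
        a, b = GeneNode(), GeneNode()
        lineage.children = [a, b]
        out = _birth_death_edge(a, t - wait, d, l, rng)
        out += _birth_death_edge(b, t - wait, d, l, rng)
        return out
    return []  # loss


def _prune(node: GeneNode) -> GeneNode | None:
    """Drop extinct subtrees and suppress unary nodes."""
    if node.is_leaf():
        return node if node.name is not None else None
    kept = [c for c in (_prune(c) for c in node.children) if c is not None]
    if not kept:
        return None
    if len(kept) == 1:
        kept[0].length += node.length
        return kept[0]
    node.children = kept
    return node


def simulate_families(config: SimulationConfig,
                      rng: np.random.Generator | None = None,
                      allow_extinct: bool = False) -> list[FamilyTruth]:
    """Simulate ``nFamilies`` gene families on the configured species tree.

    Each family starts as a single gene at the species-tree root and evolves
    by duplication and loss.  Unless ``allow_extinct`` is set, families with
    no surviving gene are redrawn (downstream stages require at least one
    member); the redraw is seed-deterministic.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sp_tree = _parse_species_tree(config.speciesTree)
    species = [lf.taxon.label for lf in sp_tree.leaf_node_iter()]

    # architecture flags, assigned up front so family identity is stable
    n = config.nFamilies
    n_tale = int(round(config.taleFraction * n))
    order = rng.permutation(n)
    tale_flags = np.zeros(n, dtype=bool)
    tale_flags[order[:n_tale]] = True
    double_flags = tale_flags & (rng.random(n) < config.doubleHdFraction)
    degrade_flags = double_flags & (rng.random(n) < config.degradeFraction)
    motif_flags = rng.random(n) < config.motifFraction

    families: list[FamilyTruth] = []
    for i in range(n):
        fam_id = f"fam{i:03d}"
        for _attempt in range(1000):
            root = GeneNode()
            counters: dict[str, int] = {}

            def descend(sp_node, lineages: list[GeneNode]) -> None:
                if not sp_node.child_nodes():
                    sp = sp_node.taxon.label
                    for ln in lineages:
                        k = counters.get(sp, 0)
                        counters[sp] = k + 1
                        ln.name = f"{sp}|{fam_id}|g{k}"
                        ln.species = sp
                    return
                for child in sp_node.child_nodes():
                    t = child.edge.length or 0.0
                    survivors: list[GeneNode] = []
                    for ln in lineages:
                        sub = GeneNode()
                        ln.children.append(sub)
                        survivors.extend(
                            _birth_death_edge(sub, t, config.duplicationRate,
                                              config.lossRate, rng)
                        )
                    descend(child, survivors)

            descend(sp_tree.seed_node, [root])
            pruned = _prune(root)
            if pruned is not None or allow_extinct:
                break
        members = []
        if pruned is not None:
            members = [(lf.species, lf.name) for lf in pruned.leaves()]
        presence = {sp: any(s == sp for s, _ in members) for sp in species}
        families.append(
            FamilyTruth(
                family_id=fam_id,
                gene_tree=pruned.to_newick() if pruned is not None else "",
                member_genes=members,
                presence_row=presence,
                hd_type="TALE" if tale_flags[i] else "nonTALE",
                double_hd=bool(double_flags[i]),
                degraded_second=bool(degrade_flags[i]),
                has_motif=bool(motif_flags[i]),
                root=pruned,
            )
        )
    return families


# ---------------------------------------------------------------------------
# sequence evolution


def evolve_residues(seq: str, t: float, rng: np.random.Generator) -> str:
    """Poisson substitution: events per site ~ Poisson(t); each event replaces
    the residue with one of the other 19 amino acids, uniformly."""
    if t <= 0.0:
        return seq
    counts = rng.poisson(t, size=len(seq))
    if not counts.any():
        return seq
    out = list(seq)
    for i in np.nonzero(counts)[0]:
        cur = out[i]
        for _ in range(counts[i]):
            j = int(rng.integers(19))
            k = _AA_IDX.get(cur, 0)
            cur = AMINO_ACIDS[j if j < k else j + 1]
        out[i] = cur
    return "".join(out)


def _scramble(seq: str, fraction: float, rng: np.random.Generator) -> str:
    n = int(round(fraction * len(seq)))
    if n == 0:
        return seq
    pos = rng.choice(len(seq), size=n, replace=False)
    out = list(seq)
    for i in pos:
        out[i] = AMINO_ACIDS[int(rng.integers(20))]
    return "".join(out)


@dataclass(frozen=True)
class DomainAnnotation:
    """A homeodomain interval on a protein (0-based half-open aa coords)."""

    hd_index: int
    aa_start: int
    aa_end: int
    hd_type: str
    intact: str  # "intact" or "degraded"


@dataclass
class GeneProtein:
    record: SequenceRecord
    domains: list[DomainAnnotation]
    family_id: str


def _random_peptide(n: int, rng: np.random.Generator) -> str:
    return "".join(AMINO_ACIDS[int(i)] for i in rng.integers(20, size=n))


def _evolve_along(root: GeneNode, seq: str, rate: float,
                  rng: np.random.Generator) -> dict[str, str]:
    """Evolve ``seq`` along the gene tree; returns leaf-name -> sequence."""
    out: dict[str, str] = {}

    def rec(node: GeneNode, s: str) -> None:
        s2 = evolve_residues(s, node.length * rate, rng)
        if node.is_leaf():
            out[node.name] = s2
        else:
            for c in node.children:
                rec(c, s2)

    rec(root, seq)
    return out


def evolve_sequences(truth: FamilyTruth, root_profiles: dict[str, str],
                     config: SimulationConfig,
                     rng: np.random.Generator):
    """Evolve protein sequences for one family.

    ``root_profiles`` must supply the family's ancestral homeodomains under
    keys ``"nonTALE"`` (60 aa) and ``"TALE"`` (63 aa).  Returns
    ``(proteins, true_alignment, motif_intervals)`` where ``true_alignment``
    maps gene id to its homeodomain row in the family's native frame (60 or
    63 columns) and ``motif_intervals`` maps gene id to the (start, end) of
    the planted C-terminal motif, when present.
    """
    if len(root_profiles.get("nonTALE", "")) != 60:
        raise ConfigError("nonTALE root profile must be 60 aa")
    if len(root_profiles.get("TALE", "")) != 63:
        raise ConfigError("TALE root profile must be 63 aa")
    if truth.root is None:
        return [], {}, {}

    profile = root_profiles[truth.hd_type]
    rate = config.substitutionRate
    hd1 = _evolve_along(truth.root, profile, rate, rng)

    hd2: dict[str, str] = {}
    if truth.double_hd:
        mult = config.degradeRateMultiplier if truth.degraded_second else 1.0
        hd2 = _evolve_along(truth.root, profile, rate * mult, rng)
        if truth.degraded_second:
            hd2 = {g: _scramble(s, config.degradeScrambleFraction, rng) for g, s in hd2.items()}

    motifs: dict[str, str] = {}
    if truth.has_motif:
        motifs = _evolve_along(truth.root, MOTIF_CONSENSUS, rate * 0.25, rng)

    linker = _random_peptide(14, rng)  # conserved within the family
    proteins: list[GeneProtein] = []
    alignment: dict[str, str] = {}
    motif_intervals: dict[str, tuple[int, int]] = {}
    for species, gene_id in truth.member_genes:
        nterm = _random_peptide(8, rng)
        parts = [nterm, hd1[gene_id]]
        domains = [DomainAnnotation(0, len(nterm), len(nterm) + len(profile),
                                    truth.hd_type, "intact")]
        if truth.double_hd:
            start2 = len(nterm) + len(profile) + len(linker)
            parts += [linker, hd2[gene_id]]
            domains.append(
                DomainAnnotation(1, start2, start2 + len(profile), truth.hd_type,
                                 "degraded" if truth.degraded_second else "intact")
            )
        if truth.has_motif:
            spacer = _random_peptide(5, rng)
            m_start = sum(len(p) for p in parts) + len(spacer)
            parts += [spacer, motifs[gene_id], _random_peptide(4, rng)]
            motif_intervals[gene_id] = (m_start, m_start + len(MOTIF_CONSENSUS))
        else:
            parts.append(_random_peptide(9, rng))
        seq = "".join(parts)
        proteins.append(
            GeneProtein(SequenceRecord(gene_id, seq, "aa", species), domains,
                        truth.family_id)
        )
        alignment[gene_id] = hd1[gene_id]
    return proteins, alignment, motif_intervals


def to_global_frame(row: str, hd_type: str) -> str:
    """Place a native-frame homeodomain row into the shared 63-column frame."""
    if hd_type == "TALE":
        if len(row) != 63:
            raise ValueError("TALE rows must be 63 aa")
        return row
    if len(row) != 60:
        raise ValueError("non-TALE rows must be 60 aa")
    return row[:TALE_INSERT_OFFSET] + "---" + row[TALE_INSERT_OFFSET:]


# ---------------------------------------------------------------------------
# scaffolds

_CODONS: dict[str, list[str]] = {}


def _codon_table() -> dict[str, list[str]]:
    global _CODONS
    if not _CODONS:
        from Bio.Data.CodonTable import standard_dna_table

        table: dict[str, list[str]] = {}
        for codon, aa in standard_dna_table.forward_table.items():
            table.setdefault(aa, []).append(codon)
        _CODONS = {aa: sorted(cods) for aa, cods in table.items()}
    return _CODONS


def reverse_translate(seq: str, rng: np.random.Generator) -> str:
    table = _codon_table()
    return "".join(table[aa][int(rng.integers(len(table[aa])))] for aa in seq)


_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def embed_in_scaffolds(proteins: Iterable[GeneProtein], config: SimulationConfig,
                       rng: np.random.Generator):
    """Reverse-translate each protein and embed it in random nucleotide flanks.

    Roughly half of the scaffolds carry the coding sequence on the reverse
    strand.  Returns ``(scaffolds, truth_table)`` where the truth table holds
    forward-strand 0-based half-open nucleotide coordinates of every planted
    homeodomain, with strand and reading frame.
    """
    nt = "ACGT"
    scaffolds: list[SequenceRecord] = []
    rows = []
    for gp in proteins:
        cds = reverse_translate(gp.record.residues, rng)
        flank_a = "".join(nt[int(i)] for i in rng.integers(4, size=config.scaffoldFlankLength))
        flank_b = "".join(nt[int(i)] for i in rng.integers(4, size=config.scaffoldFlankLength))
        strand_seq = flank_a + cds + flank_b
        strand = "-" if rng.random() < 0.5 else "+"
        forward = revcomp(strand_seq) if strand == "-" else strand_seq
        scaffold_id = gp.record.id
        scaffolds.append(SequenceRecord(scaffold_id, forward, "nt", gp.record.species))
        L = len(strand_seq)
        cds_off = len(flank_a)
        for dom in gp.domains:
            off = cds_off + 3 * dom.aa_start            # on the reading strand
            end = cds_off + 3 * dom.aa_end
            if strand == "+":
                nt_start, nt_end = off, end
            else:
                nt_start, nt_end = L - end, L - off
            rows.append({
                "geneId": gp.record.id,
                "scaffoldId": scaffold_id,
                "hdIndex": dom.hd_index,
                "hdStartNt": nt_start,
                "hdEndNt": nt_end,
                "strand": strand,
                "frame": off % 3,
                "hdType": dom.hd_type,
                "intact": dom.intact,
                "familyId": gp.family_id,
            })
    truth_table = pd.DataFrame(rows, columns=["geneId", "scaffoldId", "hdIndex",
                                              "hdStartNt", "hdEndNt", "strand",
                                              "frame", "hdType", "intact",
                                              "familyId"])
    return scaffolds, truth_table


# ---------------------------------------------------------------------------
# whole datasets

OUTGROUP_ID = "Yeast|outgroup|PHO2like"


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    families: list[FamilyTruth]
    proteins: list[GeneProtein]
    alignment: dict[str, str]           # gene id -> 63-column row (global frame)
    motif_truth: dict[str, tuple[int, int]]
    scaffolds: list[SequenceRecord]
    truth_table: pd.DataFrame
    outgroup: SequenceRecord
    root_profiles: dict[str, str]
    family_profiles: dict[str, str]

    @property
    def presence(self) -> pd.DataFrame:
        species = sorted(self.families[0].presence_row)
        data = {f.family_id: [f.presence_row[s] for s in species] for f in self.families}
        return pd.DataFrame(data, index=species).T

    def family_registry(self) -> pd.DataFrame:
        rows = [{
            "familyId": f.family_id, "hdType": f.hd_type,
            "doubleHd": int(f.double_hd), "degradedSecond": int(f.degraded_second),
            "hasMotif": int(f.has_motif), "nMembers": len(f.member_genes),
            "members": ",".join(g for _, g in f.member_genes),
        } for f in self.families]
        return pd.DataFrame(rows)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator: families, proteins, alignment, scaffolds, truth.

    Family root profiles form a chain per class: the first family's profile is
    the class consensus evolved by ``familyStepLength`` substitutions/site, and
    each subsequent profile evolves from the previous one by the same step, so
    neighbouring families stay within reach of an iterative homology search.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    families = simulate_families(config, rng=rng)
    roots = default_root_profiles()

    family_profiles: dict[str, str] = {}
    chain = dict(roots)
    for fam in families:
        prev = chain[fam.hd_type]
        prof = evolve_residues(prev, config.familyStepLength, rng)
        chain[fam.hd_type] = prof
        family_profiles[fam.family_id] = prof

    proteins: list[GeneProtein] = []
    alignment: dict[str, str] = {}
    motif_truth: dict[str, tuple[int, int]] = {}
    for fam in families:
        profs = dict(roots)
        profs[fam.hd_type] = family_profiles[fam.family_id]
        fam_proteins, fam_aln, fam_motifs = evolve_sequences(fam, profs, config, rng)
        proteins.extend(fam_proteins)
        for gid, row in fam_aln.items():
            alignment[gid] = to_global_frame(row, fam.hd_type)
        motif_truth.update(fam_motifs)

    scaffolds, truth_table = embed_in_scaffolds(proteins, config, rng)
    outgroup_seq = evolve_residues(roots["nonTALE"], 2.5, rng)
    outgroup = SequenceRecord(OUTGROUP_ID, outgroup_seq, "aa", "Yeast")
    return SimulatedDataset(config, families, proteins, alignment, motif_truth,
                            scaffolds, truth_table, outgroup, roots,
                            family_profiles)


def write_dataset(dataset: SimulatedDataset, outdir) -> dict[str, str]:
    """Write scaffolds, proteins, true alignment and truth tables to ``outdir``.

    Returns a name -> path map.  All outputs are plain text (FASTA / TSV).
    """
    from pathlib import Path

    from .io import write_fasta, write_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "scaffolds": outdir / "scaffolds.fasta",
        "proteins": outdir / "proteins.fasta",
        "alignment": outdir / "true_alignment.fasta",
        "truth": outdir / "truth_table.tsv",
        "families": outdir / "family_registry.tsv",
        "presence": outdir / "presence_matrix.tsv",
        "outgroup": outdir / "outgroup.fasta",
    }
    write_fasta(dataset.scaffolds, paths["scaffolds"])
    write_fasta([gp.record for gp in dataset.proteins], paths["proteins"])
    aln_records = [SequenceRecord(gid, row, "aa") for gid, row in sorted(dataset.alignment.items())]
    aln_records.append(SequenceRecord(dataset.outgroup.id,
                                      to_global_frame(dataset.outgroup.residues, "nonTALE"), "aa"))
    write_fasta(aln_records, paths["alignment"])
    write_tsv(dataset.truth_table, paths["truth"],
              comment="planted homeodomain coordinates (0-based half-open, forward strand)")
    write_tsv(dataset.family_registry(), paths["families"], comment="simulated family truth")
    presence = dataset.presence.astype(int)
    presence.insert(0, "familyId", presence.index)
    write_tsv(presence, paths["presence"], comment="family presence/absence by species")
    write_fasta([dataset.outgroup], paths["outgroup"])
    return {k: str(v) for k, v in paths.items()}
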
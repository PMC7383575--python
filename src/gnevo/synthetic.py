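"""Synthetic genomes, trees, traits and protein families with planted truth.

The generator emulates the statistical structure the pipeline assumes:
multi-scaffold genomes whose target genes sit at known interior ranks;
per-gene Bernoulli placement of Pfam-style domains, with an elevated
foreground probability inside the neighbourhoods of one designated clade
(the planted association) against a genome-wide background probability;
a Yule (pure-birth) gene tree over the targets; binary tailoring traits
evolving by a two-state Markov chain along that tree; and a protein
family diverging under an equal-frequency 20-state substitution chain, so
expected pairwise identity has a closed form in the patristic distance:

    E[identity](d) = 1/20 + (19/20) * exp(-r * d).

Everything is a pure function of the :class:`SimulationConfig` (the seed
included), so regenerated datasets are byte-identical.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .io_formats import (
    AnnotatedGenome,
    DomainHit,
    GeneRecord,
    write_domain_table,
    write_protein_fasta,
    _assign_ranks,
)

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
TARGET_FAMILY = "SQHop_cyclase"  # scaffold-generating target-gene marker

BACKGROUND_FAMILIES = (
    "Fer4", "PPR", "Pkinase", "Myb_DNA-binding", "LRR_8", "UDPGT",
    "AP2", "WD40", "RRM_1", "zf-C3HC4", "Peptidase_C48", "DUF4283",
)

TAILORING_DOMAINS = (
    ("p450", "CYP705A"),
    ("p450", "CYP708A"),
    ("p450", "CYP702A"),
    ("Transferase", "ACT_IIIa"),
)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the organism-scale setting the pipeline targets:
    13 genomes (one clade-assigned target gene each by default), flank-5
    windows, a planted clade association at foreground probability 0.9
    against a 0.02 background, and mild trait gain/loss rates giving a
    handful of events on the tree.
    """

    seed: int = 0
    n_genomes: int = 13
    scaffolds_per_genome: int = 2
    genes_per_scaffold: int = 40
    n_targets_per_genome: int = 1
    flank: int = 5
    domain_palette: tuple[tuple[str, str], ...] = tuple(
        (f, "") for f in BACKGROUND_FAMILIES
    ) + TAILORING_DOMAINS
    planted_domain: str = "CYP705A"
    planted_clade: str = "cladeII"
    p_background: float = 0.02
    p_foreground: float = 0.9
    trait_gain_rate: float = 0.03  # per unit branch length
    trait_loss_rate: float = 0.01
    protein_length: int = 120
    substitution_rate: float = 0.3  # expected substitutions/site/unit length
    gene_length_nt: int = 363
    intergenic_nt: int = 60
    clade_names: tuple[str, str] = ("cladeI", "cladeII")

    def __post_init__(self) -> None:
        for p in (self.p_background, self.p_foreground):
            if not 0.0 <= p <= 1.0:
                raise ValueError("placement probabilities must lie in [0, 1]")
        if min(self.trait_gain_rate, self.trait_loss_rate, self.substitution_rate) < 0:
            raise ValueError("rates must be >= 0")


@dataclass
class GroundTruth:
    planted_associations: list[dict] = field(default_factory=list)
    true_trait_events: dict[str, list[dict]] = field(default_factory=dict)
    true_pairwise_identity: dict[str, float] = field(default_factory=dict)
    clade_of_target: dict[str, str] = field(default_factory=dict)
    target_windows: dict[str, list[str]] = field(default_factory=dict)
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def simulate_tree(n_leaves: int, seed: int, birth_rate: float = 1.0) -> dendropy.Tree:
    """Yule (pure-birth) tree with ``n_leaves`` leaves.

    Starts from the root split (two lineages), so exactly
    ``n_leaves - 2`` further branching events are drawn; leaf labels are
    ``T0..T{n-1}`` in birth order. Deterministic under ``seed``.
    """
    if n_leaves < 2:
        raise ValueError("n_leaves must be >= 2")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    root = tree.seed_node
    children = [root.new_child(edge_length=0.0), root.new_child(edge_length=0.0)]
    tips = list(children)
    while len(tips) < n_leaves:
        wait = rng.exponential(1.0 / (birth_rate * len(tips)))
        for tip in tips:
            tip.edge.length += wait
        idx = rng.integers(len(tips))
        parent = tips.pop(int(idx))
        tips.append(parent.new_child(edge_length=0.0))
        tips.append(parent.new_child(edge_length=0.0))
    # final waiting time so terminal branches are not zero
    wait = rng.exponential(1.0 / (birth_rate * len(tips)))
    for tip in tips:
        tip.edge.length += wait
    for i, tip in enumerate(tips):
        tip.taxon = taxa.new_taxon(label=f"T{i}")
    return tree


def evolve_binary_trait(
    tree: dendropy.Tree,
    gain_rate: float,
    loss_rate: float,
    root_state: int,
    seed: int,
) -> tuple[dict[str, int], list[dict]]:
    """Two-state continuous-time Markov chain along every branch.

    Waiting times between state flips are exponential with the rate of the
    current state (gain rate out of 0, loss rate out of 1); every realised
    flip is recorded as a gain or loss on its branch. Returns leaf states
    and the event list.
    """
    if gain_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    states: dict[int, int] = {id(tree.seed_node): int(root_state)}
    events: list[dict] = []
    for i, node in enumerate(tree.preorder_node_iter()):
        if node.parent_node is None:
            continue
        state = states[id(node.parent_node)]
        t = node.edge.length or 0.0
        pos = 0.0
        while True:
            rate = gain_rate if state == 0 else loss_rate
            if rate == 0:
                break
            pos += rng.exponential(1.0 / rate)
            if pos >= t:
                break
            label = node.taxon.label if node.is_leaf() else f"node{i}"
            events.append(
                {
                    "branch": label,
                    "event": "gain" if state == 0 else "loss",
                    "time": pos,
                }
            )
            state = 1 - state
        states[id(node)] = state
    leaf_states = {
        leaf.taxon.label: states[id(leaf)] for leaf in tree.leaf_node_iter()
    }
    return leaf_states, events


def transition_probability_01(gain_rate: float, loss_rate: float, t: float) -> float:
    """Closed-form P(state 1 at time t | state 0 at 0) of the two-state chain."""
    total = gain_rate + loss_rate
    if total == 0:
        return 0.0
    return (gain_rate / total) * (1.0 - math.exp(-total * t))


def expected_identity(rate: float, patristic_distance: float) -> float:
    """Expected pairwise identity of the 20-state equal-frequency chain."""
    return 1.0 / 20.0 + (19.0 / 20.0) * math.exp(-rate * patristic_distance)


def simulate_protein_family(
    tree: dendropy.Tree, length: int, substitution_rate: float, seed: int
) -> dict[str, str]:
    """Evolve one protein family along the tree.

    Each site on a branch of length ``t`` changes to a uniformly chosen
    *different* residue with probability ``(19/20) * (1 - exp(-r t))`` —
    the visible-change probability of the equal-frequency 20-state chain,
    which makes :func:`expected_identity` exact over patristic distance.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 20, size=length)
    seqs: dict[int, np.ndarray] = {id(tree.seed_node): root_seq}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent_seq = seqs[id(node.parent_node)]
        t = node.edge.length or 0.0
        p_change = (19.0 / 20.0) * (1.0 - math.exp(-substitution_rate * t))
        seq = parent_seq.copy()
        changed = rng.random(length) < p_change
        if changed.any():
            # uniform over the 19 alternatives of each changed site
            offsets = rng.integers(1, 20, size=int(changed.sum()))
            seq[changed] = (seq[changed] + offsets) % 20
        seqs[id(node)] = seq
    return {
        leaf.taxon.label: "".join(AMINO_ACIDS[seqs[id(leaf)]])
        for leaf in tree.leaf_node_iter()
    }


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[rng.integers(0, 20, size=length)])


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genomes: list[AnnotatedGenome]
    hits: list[DomainHit]
    tree: dendropy.Tree
    truth: GroundTruth
    target_ids: list[str]
    reference_labels: dict[str, str]  # one reference leaf per clade
    trait_states: dict[str, dict[str, int]] = field(default_factory=dict)
    _dna: dict[tuple[str, str], str] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the dataset in the formats the pipeline consumes."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for genome in self.genomes:
            p = out / f"{genome.genome_id}.gbk"
            records = []
            for scaffold_id in genome.scaffolds:
                genes = genome.scaffold(scaffold_id)
                seq = self._dna[(genome.genome_id, scaffold_id)]
                rec = SeqRecord(
                    Seq(seq), id=scaffold_id, name=scaffold_id,
                    description=f"synthetic scaffold of {genome.genome_id}",
                )
                rec.annotations["molecule_type"] = "DNA"
                for g in genes:
                    quals = {"locus_tag": [g.gene_id], "translation": [g.protein]}
                    rec.features.append(
                        SeqFeature(
                            SimpleLocation(g.start - 1, g.end, strand=g.strand),
                            type="CDS",
                            qualifiers=quals,
                        )
                    )
                records.append(rec)
            with open(p, "w", encoding="utf-8") as fh:
                SeqIO.write(records, fh, "genbank")
            paths[genome.genome_id] = p
        write_domain_table(self.hits, out / "hits.tsv")
        paths["hits"] = out / "hits.tsv"
        with open(out / "tree.nwk", "w", encoding="utf-8") as fh:
            fh.write(self.tree.as_string(schema="newick", suppress_rooting=True))
        paths["tree"] = out / "tree.nwk"
        all_genes = [g for genome in self.genomes for g in genome.genes]
        write_protein_fasta(all_genes, out / "proteins.faa")
        paths["proteins"] = out / "proteins.faa"
        with open(out / "ground_truth.json", "w", encoding="utf-8") as fh:
            fh.write(self.truth.to_json())
        paths["ground_truth"] = out / "ground_truth.json"
        with open(out / "reference_labels.tsv", "w", encoding="utf-8") as fh:
            fh.write("leaf_name\tlabel\n")
            for leaf, label in sorted(self.reference_labels.items()):
                fh.write(f"{leaf}\t{label}\n")
        paths["reference_labels"] = out / "reference_labels.tsv"
        return paths


def generate_dataset(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> SyntheticDataset:
    """Build a full synthetic dataset with planted ground truth.

    Targets are placed at evenly spaced interior ranks (windows never
    overlap or hit a scaffold edge at the default sizes); the Yule tree's
    two root subtrees define the two clades; the planted domain is placed
    at ``p_foreground`` inside the planted clade's windows and every
    palette domain at ``p_background`` genome-wide. Target translations
    evolve along the tree; all other proteins are i.i.d. random.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_targets = cfg.n_genomes * cfg.n_targets_per_genome
    tree = simulate_tree(n_targets, seed=int(rng.integers(2**31)))

    # clades = the two root subtrees, in leaf-birth order
    root_children = tree.seed_node.child_nodes()
    clade_of_leaf: dict[str, str] = {}
    for child, clade in zip(root_children, cfg.clade_names):
        for leaf in child.leaf_iter():
            clade_of_leaf[leaf.taxon.label] = clade

    target_proteins = simulate_protein_family(
        tree, cfg.protein_length, cfg.substitution_rate, seed=int(rng.integers(2**31))
    )

    # trait evolution for each tailoring domain
    truth = GroundTruth(seed=cfg.seed)
    trait_states: dict[str, dict[str, int]] = {}
    for family, subfamily in TAILORING_DOMAINS:
        name = subfamily or family
        states, events = evolve_binary_trait(
            tree,
            cfg.trait_gain_rate,
            cfg.trait_loss_rate,
            root_state=0,
            seed=int(rng.integers(2**31)),
        )
        trait_states[name] = states
        truth.true_trait_events[name] = events

    pdm = tree.phylogenetic_distance_matrix()
    for ta, tb in itertools.combinations(sorted(tree.taxon_namespace, key=lambda t: t.label), 2):
        d = pdm.patristic_distance(ta, tb)
        truth.true_pairwise_identity[f"{ta.label}|{tb.label}"] = expected_identity(
            cfg.substitution_rate, d
        )

    if cfg.p_foreground != cfg.p_background:
        truth.planted_associations.append(
            {
                "clade": cfg.planted_clade,
                "domain": cfg.planted_domain,
                "p_foreground": cfg.p_foreground,
                "p_background": cfg.p_background,
            }
        )

    # assign targets (tree leaves) to genomes round-robin, in leaf order
    leaf_labels = [f"T{i}" for i in range(n_targets)]
    genome_of_leaf = {
        label: f"genome{(i % cfg.n_genomes):02d}" for i, label in enumerate(leaf_labels)
    }

    window = 2 * cfg.flank + 1
    spacing = cfg.genes_per_scaffold // cfg.n_targets_per_genome
    if spacing < window + 2 or cfg.genes_per_scaffold < window + 2:
        raise ValueError(
            "scaffold too short for non-overlapping interior target windows"
        )

    genomes: list[AnnotatedGenome] = []
    hits: list[DomainHit] = []
    dna: dict[tuple[str, str], str] = {}
    target_ids: list[str] = []
    rename: dict[str, str] = {}

    leaves_by_genome: dict[str, list[str]] = {}
    for label in leaf_labels:
        leaves_by_genome.setdefault(genome_of_leaf[label], []).append(label)

    for gi in range(cfg.n_genomes):
        genome_id = f"genome{gi:02d}"
        genes: list[GeneRecord] = []
        genome_leaves = leaves_by_genome.get(genome_id, [])
        # targets all placed on scaffold 0, evenly spaced interior ranks
        target_rank_of_leaf = {
            label: cfg.flank + 1 + j * spacing for j, label in enumerate(genome_leaves)
        }
        if target_rank_of_leaf and max(target_rank_of_leaf.values()) + cfg.flank >= cfg.genes_per_scaffold:
            raise ValueError("target window exceeds scaffold")
        for si in range(cfg.scaffolds_per_genome):
            scaffold_id = f"{genome_id}_s{si}"
            rank_to_leaf = (
                {r: lf for lf, r in target_rank_of_leaf.items()} if si == 0 else {}
            )
            pos = 1
            for rank in range(cfg.genes_per_scaffold):
                start = pos
                end = pos + cfg.gene_length_nt - 1
                pos = end + 1 + cfg.intergenic_nt
                strand = 1 if rng.random() < 0.5 else -1
                if rank in rank_to_leaf:
                    leaf = rank_to_leaf[rank]
                    gene_id = f"{genome_id}_osc_{leaf}"
                    rename[leaf] = gene_id
                    target_ids.append(gene_id)
                    protein = target_proteins[leaf]
                else:
                    gene_id = f"{genome_id}_s{si}_g{rank:03d}"
                    protein = _random_protein(rng, cfg.protein_length)
                genes.append(
                    GeneRecord(gene_id, scaffold_id, start, end, strand, rank, protein)
                )
            dna[(genome_id, scaffold_id)] = _random_dna(
                rng, genes[-1].end if genes else 1
            )

        genome = AnnotatedGenome(genome_id, _assign_ranks(genes))

        # domain placement
        foreground_genes: set[str] = set()
        for leaf, r in target_rank_of_leaf.items():
            if clade_of_leaf[leaf] == cfg.planted_clade:
                scaffold = genome.scaffold(f"{genome_id}_s0")
                lo, hi = max(r - cfg.flank, 0), min(r + cfg.flank, len(scaffold) - 1)
                members = [g.gene_id for g in scaffold[lo : hi + 1]]
                foreground_genes.update(members)
                truth.target_windows[rename[leaf]] = members
            else:
                scaffold = genome.scaffold(f"{genome_id}_s0")
                lo, hi = max(r - cfg.flank, 0), min(r + cfg.flank, len(scaffold) - 1)
                truth.target_windows[rename[leaf]] = [
                    g.gene_id for g in scaffold[lo : hi + 1]
                ]

        genome_target_ids = set(rename[lf] for lf in genome_leaves)
        genome_hits: list[DomainHit] = []
        for g in genome.genes:
            if g.gene_id in genome_target_ids:
                genome_hits.append(DomainHit(g.gene_id, TARGET_FAMILY, "", 250.0))
            for family, subfamily in cfg.domain_palette:
                name = subfamily or family
                p = cfg.p_background
                if name == cfg.planted_domain and g.gene_id in foreground_genes:
                    p = cfg.p_foreground
                if rng.random() < p:
                    genome_hits.append(
                        DomainHit(g.gene_id, family, subfamily, float(rng.integers(50, 400)))
                    )
        genome.attach_hits(genome_hits, strict=True)
        hits.extend(genome_hits)
        genomes.append(genome)

    # rename tree leaves to target gene ids
    for leaf in tree.leaf_node_iter():
        leaf.taxon.label = rename[leaf.taxon.label]
    truth.clade_of_target = {rename[lf]: c for lf, c in clade_of_leaf.items()}
    truth.true_pairwise_identity = {
        "|".join(rename[x] for x in key.split("|")): v
        for key, v in truth.true_pairwise_identity.items()
    }
    for name, events in truth.true_trait_events.items():
        for ev in events:
            if ev["branch"] in rename:
                ev["branch"] = rename[ev["branch"]]
    trait_states = {
        name: {rename[lf]: s for lf, s in states.items()}
        for name, states in trait_states.items()
    }

    # one reference leaf per clade: the lexicographically first target
    reference_labels: dict[str, str] = {}
    for clade in cfg.clade_names:
        members = sorted(t for t, c in truth.clade_of_target.items() if c == clade)
        if members:
            reference_labels[members[0]] = clade

    dataset = SyntheticDataset(
        config=cfg,
        genomes=genomes,
        hits=hits,
        tree=tree,
        truth=truth,
        target_ids=sorted(target_ids),
        reference_labels=reference_labels,
        trait_states=trait_states,
        _dna=dna,
    )
    if out_dir is not None:
        dataset.write(out_dir)
    return dataset
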
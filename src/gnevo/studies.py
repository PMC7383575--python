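"""Replicated simulation studies of the pipeline's statistical behaviour.

These harnesses quantify, under controlled synthetic conditions, the
operating characteristics a user should expect of the enrichment test and
the parsimony reconstruction:

* **Type-I error** — with no planted association (foreground placement
  equal to background), how often a domain reaches Bonferroni-adjusted
  significance, for both the naive and the conservative count.
* **Power** — with a strong planted association, how often the planted
  domain is detected.
* **Event recovery** — how often the parsimony score equals the number of
  gain/loss events actually simulated on the tree, in the low-rate regime
  where parsimony is expected to be consistent.

The default study sizes (5,000 background genes, 20 neighbourhoods of 11
genes, background placement probability 0.02, foreground 0.9, 39-leaf
trees) are the package's reference conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ancestral import TraitTree, fitch_parsimony
from .enrichment import run_enrichment
from .io_formats import AnnotatedGenome, DomainHit, GeneRecord
from .neighbourhoods import extract_neighbourhoods
from .synthetic import simulate_tree

import pandas as pd


def _flat_genome(n_genes: int, genome_id: str = "sim") -> AnnotatedGenome:
    genes = [
        GeneRecord(f"{genome_id}_g{i:05d}", "s0", 1 + 400 * i, 300 + 400 * i, 1, i)
        for i in range(n_genes)
    ]
    return AnnotatedGenome(genome_id, genes)


@dataclass
class EnrichmentStudyResult:
    n_replicates: int
    n_tests: int
    fpr_naive: float
    fpr_conservative: float
    detection_rate_naive: float
    detection_rate_conservative: float


def enrichment_study(
    n_replicates: int,
    seed: int,
    n_genes: int = 5000,
    n_gns: int = 20,
    flank: int = 5,
    n_domains: int = 30,
    p_background: float = 0.02,
    p_foreground: float | None = None,
    threshold: float = 0.01,
) -> EnrichmentStudyResult:
    """Replicated enrichment runs on a fixed gene universe.

    One clade of ``n_gns`` neighbourhoods (11 genes each at the default
    flank) sits in a ``n_genes``-gene universe; every one of ``n_domains``
    domains is placed per-gene Bernoulli at ``p_background``, and domain
    ``D00`` additionally at ``p_foreground`` inside the clade windows when
    a foreground probability is given (``None`` = null study). The clade
    leaves form one 20-leaf subtree so the conservative collapsing is
    exercised. Returns false-positive rates over non-planted domains and
    detection rates for the planted one.
    """
    rng = np.random.default_rng(seed)
    genome = _flat_genome(n_genes)
    spacing = 2 * flank + 2
    targets = [f"sim_g{(flank + spacing * i):05d}" for i in range(n_gns)]
    gns = extract_neighbourhoods(genome, targets, flank)
    assert all(gn.n_genes == 2 * flank + 1 for gn in gns)
    clade_genes = [gid for gn in gns for gid in gn.member_gene_ids]
    clade_index = {gid: True for gid in clade_genes}
    leaf_to_gn = {t: gn.gn_id for gn in gns for t in gn.center_gene_ids}

    tree = simulate_tree(n_gns, seed=seed)
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = targets[i]

    domains = [f"D{i:02d}" for i in range(n_domains)]
    planted = "D00" if p_foreground is not None else None

    gene_ids = [g.gene_id for g in genome.genes]
    n_false = 0
    n_tests = 0
    hits_naive = 0
    hits_cons = 0
    fp_naive = 0
    fp_cons = 0
    for _ in range(n_replicates):
        hits: list[DomainHit] = []
        for d in domains:
            draw = rng.random(n_genes) < p_background
            if d == planted:
                fg = rng.random(n_genes) < p_foreground
                for i, gid in enumerate(gene_ids):
                    if (gid in clade_index and fg[i]) or draw[i]:
                        hits.append(DomainHit(gid, d, "", 100.0))
            else:
                for i in np.flatnonzero(draw):
                    hits.append(DomainHit(gene_ids[i], d, "", 100.0))
        genome.hits = []
        genome.attach_hits(hits)
        for mode, counters in (("naive", "n"), ("conservative", "c")):
            results = run_enrichment(
                [genome], {"clade": gns}, tree, leaf_to_gn,
                mode=mode, threshold=threshold,
            )
            sig = {r.domain for r in results if r.significant}
            nulls = {r.domain for r in results} - ({planted} if planted else set())
            if mode == "naive":
                n_tests += len(nulls)
                fp_naive += len(sig & nulls)
                hits_naive += int(planted in sig) if planted else 0
            else:
                fp_cons += len(sig & nulls)
                hits_cons += int(planted in sig) if planted else 0

    return EnrichmentStudyResult(
        n_replicates=n_replicates,
        n_tests=n_tests,
        fpr_naive=fp_naive / n_tests if n_tests else 0.0,
        fpr_conservative=fp_cons / n_tests if n_tests else 0.0,
        detection_rate_naive=hits_naive / n_replicates if planted else float("nan"),
        detection_rate_conservative=hits_cons / n_replicates if planted else float("nan"),
    )


def event_recovery_study(
    n_replicates: int,
    seed: int,
    n_leaves: int = 39,
    gain_rate: float = 0.03,
    loss_rate: float = 0.01,
) -> float:
    """Fraction of replicates where the parsimony score equals the number
    of simulated gain/loss events.

    Each replicate draws a fresh Yule tree and evolves one binary trait at
    low rates (a handful of expected events on a 39-leaf tree), the regime
    the reconstruction targets.
    """
    from .synthetic import evolve_binary_trait

    rng = np.random.default_rng(seed)
    recovered = 0
    for _ in range(n_replicates):
        tree = simulate_tree(n_leaves, seed=int(rng.integers(2**31)))
        states, events = evolve_binary_trait(
            tree, gain_rate, loss_rate, root_state=0, seed=int(rng.integers(2**31))
        )
        traits = pd.DataFrame({"d": pd.Series(states)})
        score = fitch_parsimony(TraitTree(tree=tree, traits=traits), "d").score
        if score == len(events):
            recovered += 1
    return recovered / n_replicates
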
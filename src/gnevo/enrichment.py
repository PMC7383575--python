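"""Domain enrichment of GN content versus the genomic background.

For each clade of the target-gene tree, every domain observed in that
clade's neighbourhoods is tested with a one-tailed hypergeometric test
(equivalently a one-tailed exact Fisher test): out of ``N`` genes in the
background universe of which ``K`` carry the domain, the clade's GNs hold
``n`` genes of which ``k`` carry it, and the reported p-value is
``P(X >= k)``. Bonferroni correction uses the number of domains tested for
that clade.

Close phylogenetic relatedness of the sampled genomes inflates ``k`` with
vertically inherited copies. The *conservative* variant counters this by
collapsing every maximal monophyletic group of leaves that all share the
trait down to the single leaf with the highest domain count, summing those
maxima instead of all leaf counts. Only ``k`` is reduced; ``n`` is not, so
the variant is strictly conservative (never a smaller p-value than the
naive count).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
from scipy.stats import hypergeom

from .io_formats import AnnotatedGenome
from .neighbourhoods import GenomeNeighbourhood

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    domain: str
    clade: str
    k: int
    K: int
    n: int
    N: int
    p_raw: float
    p_adj: float
    m: int
    significant: bool
    level: str = "family"
    mode: str = "naive"
    genome_id: str | None = None  # None = pooled universe


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``N`` genes total, ``K`` marked, ``n`` drawn, ``k`` observed successes.
    Equals 1 when k == 0.
    """
    if not (0 <= k <= min(K, n) and n <= N and K <= N):
        raise ValueError(f"invalid hypergeometric input k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bonferroni(p_raw: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, m * p_raw)."""
    if not (0.0 <= p_raw <= 1.0):
        raise ValueError(f"p_raw out of [0,1]: {p_raw}")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p_raw)


def conservative_k(
    tree: dendropy.Tree,
    clade_leaves: Iterable[str],
    leaf_counts: Mapping[str, int],
) -> int:
    """Phylogeny-collapsed success count.

    Within the tree restricted to ``clade_leaves``, leaves with a positive
    domain count are partitioned into maximal monophyletic groups in which
    *every* leaf has a positive count; each group contributes only its
    highest leaf count. Leaves with count 0 contribute nothing; leaves
    absent from ``leaf_counts`` are treated as 0 (logged).
    """
    clade_leaves = set(clade_leaves)
    tree_leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    unknown = clade_leaves - tree_leaves
    if unknown:
        raise ValueError(f"clade leaves not in tree: {sorted(unknown)}")
    for name in clade_leaves - set(leaf_counts):
        logger.warning("leaf %s missing from counts; treated as 0", name)

    counts = {name: int(leaf_counts.get(name, 0)) for name in clade_leaves}
    if any(c < 0 for c in counts.values()):
        raise ValueError("leaf counts must be >= 0")

    # Per node, over the clade leaves below it: how many there are, whether
    # all have positive counts, and the highest count. Nodes with no clade
    # leaves below are transparent in the induced subtree; an ancestor with
    # the same clade-leaf count as its descendant is a suppressed
    # unifurcation of that induced subtree and is skipped when locating the
    # induced parent.
    info: dict[int, tuple[int, bool, int]] = {}  # id -> (n_clade, all_pos, max_count)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            name = node.taxon.label
            if name in counts:
                info[id(node)] = (1, counts[name] > 0, counts[name])
            else:
                info[id(node)] = (0, True, 0)
        else:
            n_clade, all_pos, max_count = 0, True, 0
            for child in node.child_nodes():
                cn, cpos, cmax = info[id(child)]
                n_clade += cn
                if cn > 0:
                    all_pos = all_pos and cpos
                    max_count = max(max_count, cmax)
            info[id(node)] = (n_clade, all_pos, max_count)

    # A node roots a maximal all-positive monophyletic group when all clade
    # leaves below it are positive and its induced parent (nearest ancestor
    # holding strictly more clade leaves) is not all-positive, or is absent.
    total = 0
    for node in tree.preorder_node_iter():
        n_clade, all_pos, max_count = info[id(node)]
        if n_clade == 0 or not all_pos:
            continue
        anc = node.parent_node
        while anc is not None and info[id(anc)][0] == n_clade:
            anc = anc.parent_node
        if anc is None or not info[id(anc)][1]:
            total += max_count
    return total


def naive_k(clade_leaves: Iterable[str], leaf_counts: Mapping[str, int]) -> int:
    return sum(int(leaf_counts.get(name, 0)) for name in clade_leaves)


def _gene_domains(
    genomes: Sequence[AnnotatedGenome], level: str
) -> dict[str, set[str]]:
    """gene_id -> set of domain names at the chosen level, pooled."""
    out: dict[str, set[str]] = {}
    for genome in genomes:
        for h in genome.hits:
            out.setdefault(h.gene_id, set()).add(h.name_at(level))
    return out


def run_enrichment(
    genomes: Sequence[AnnotatedGenome],
    gns_by_clade: Mapping[str, Sequence[GenomeNeighbourhood]],
    tree: dendropy.Tree | None = None,
    leaf_to_gn: Mapping[str, str] | None = None,
    level: str = "family",
    mode: str = "naive",
    threshold: float = 0.01,
    per_genome: bool = False,
) -> list[EnrichmentResult]:
    """Test every domain observed in each clade's GNs for enrichment.

    Counting unit is the gene: a gene with one or more hits of a domain
    counts once. The background universe pools all genes of all supplied
    genomes (``per_genome=True`` additionally emits one result set per
    genome, restricted to that genome's genes and GNs). ``mode`` selects
    the naive or the phylogeny-conservative success count; the conservative
    mode requires ``tree`` and ``leaf_to_gn``.
    """
    if mode not in ("naive", "conservative"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "conservative" and (tree is None or leaf_to_gn is None):
        raise ValueError("conservative mode requires tree and leaf_to_gn")

    universes: list[tuple[str | None, Sequence[AnnotatedGenome]]] = [(None, genomes)]
    if per_genome:
        universes += [(g.genome_id, [g]) for g in genomes]

    results: list[EnrichmentResult] = []
    for genome_id, universe in universes:
        gene_domains = _gene_domains(universe, level)
        universe_gene_ids = [g.gene_id for genome in universe for g in genome.genes]
        N = len(universe_gene_ids)
        domain_K: dict[str, int] = {}
        for gid in universe_gene_ids:
            for d in gene_domains.get(gid, ()):
                domain_K[d] = domain_K.get(d, 0) + 1

        for clade, gns in gns_by_clade.items():
            if genome_id is not None:
                gns = [gn for gn in gns if gn.genome_id == genome_id]
            member_ids: list[str] = []
            seen: set[str] = set()
            for gn in gns:
                for gid in gn.member_gene_ids:
                    if gid not in seen:
                        seen.add(gid)
                        member_ids.append(gid)
            if not member_ids:
                logger.warning("clade %s has no GN genes in universe %s; skipped",
                               clade, genome_id or "pooled")
                continue
            n = len(member_ids)
            observed: dict[str, int] = {}
            for gid in member_ids:
                for d in gene_domains.get(gid, ()):
                    observed[d] = observed.get(d, 0) + 1
            if not observed:
                continue
            m = len(observed)

            clade_leaves: list[str] = []
            gn_members: dict[str, set[str]] = {gn.gn_id: set(gn.member_gene_ids) for gn in gns}
            if mode == "conservative":
                gn_ids = set(gn_members)
                clade_leaves = [lf for lf, g in leaf_to_gn.items() if g in gn_ids]

            for domain in sorted(observed):
                if mode == "naive":
                    k = observed[domain]
                else:
                    leaf_counts = {}
                    for lf in clade_leaves:
                        members = gn_members[leaf_to_gn[lf]]
                        leaf_counts[lf] = sum(
                            1 for gid in members if domain in gene_domains.get(gid, ())
                        )
                    k = conservative_k(tree, clade_leaves, leaf_counts)
                    k = min(k, observed[domain])  # guard: collapsing never exceeds naive
                K = domain_K[domain]
                p_raw = hypergeom_upper_tail(min(k, min(K, n)), K, n, N)
                p_adj = bonferroni(p_raw, m)
                results.append(
                    EnrichmentResult(
                        domain=domain, clade=clade, k=k, K=K, n=n, N=N,
                        p_raw=p_raw, p_adj=p_adj, m=m,
                        significant=p_adj < threshold,
                        level=level, mode=mode, genome_id=genome_id,
                    )
                )
    results.sort(key=lambda r: (r.genome_id or "", r.clade, r.p_adj, r.domain))
    return results


def results_to_dataframe(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    cols = ["clade", "domain", "level", "mode", "genome_id",
            "k", "K", "n", "N", "m", "p_raw", "p_adj", "significant"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in results], columns=cols)
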
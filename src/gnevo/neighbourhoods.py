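"""Genome neighbourhoods: extraction, merging, filtering and classification.

A genome neighbourhood (GN) is the window of genes extending ``flank``
genes either side of a target gene (default 5, so most GNs hold 11 genes).
Windows clipped by a scaffold edge are flagged ``truncated``; windows of
nearby targets whose rank intervals overlap (or touch, by default) merge
transitively into one larger GN carrying every such target as a center.

Clade labels for the target-gene tree are propagated from a reference set
of annotated leaves: each unlabeled leaf takes the label of the smallest
enclosing clade whose reference leaves agree, and is flagged ambiguous
when that clade mixes labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy

from .io_formats import AnnotatedGenome, DomainHit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenomeNeighbourhood:
    """An ordered, rank-contiguous window of genes around >=1 target gene."""

    gn_id: str
    genome_id: str
    scaffold_id: str
    center_gene_ids: tuple[str, ...]
    member_gene_ids: tuple[str, ...]
    flank: int
    merged: bool
    truncated: bool
    first_rank: int
    last_rank: int

    @property
    def n_genes(self) -> int:
        return len(self.member_gene_ids)


@dataclass(frozen=True)
class CladeLabel:
    leaf_name: str
    label: str
    source: str  # "reference" | "propagated" | "ambiguous"


def extract_neighbourhoods(
    genome: AnnotatedGenome,
    target_gene_ids: Sequence[str],
    flank: int = 5,
    merge_adjacent: bool = True,
) -> list[GenomeNeighbourhood]:
    """Extract the GN around each target and merge overlapping windows.

    Rank intervals ``[r - flank, r + flank]`` are clipped to the scaffold;
    intervals on one scaffold that overlap — or exactly touch, when
    ``merge_adjacent`` — are merged transitively. Returned GNs are sorted
    by (scaffold, first rank). Merging is independent of target order.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    for t in target_gene_ids:
        if t not in genome:
            raise ValueError(f"unknown target gene {t!r} in genome {genome.genome_id}")

    by_scaffold: dict[str, list[tuple[int, int, str, bool]]] = {}
    for t in sorted(set(target_gene_ids)):
        g = genome.gene(t)
        scaffold = genome.scaffold(g.scaffold_id)
        lo, hi = g.rank - flank, g.rank + flank
        clipped_lo, clipped_hi = max(lo, 0), min(hi, len(scaffold) - 1)
        truncated = (clipped_lo != lo) or (clipped_hi != hi)
        by_scaffold.setdefault(g.scaffold_id, []).append((clipped_lo, clipped_hi, t, truncated))

    gap = 1 if merge_adjacent else 0
    out: list[GenomeNeighbourhood] = []
    for scaffold_id, windows in by_scaffold.items():
        windows.sort()
        scaffold = genome.scaffold(scaffold_id)
        # transitive merge of sorted intervals
        groups: list[list[tuple[int, int, str, bool]]] = []
        for w in windows:
            if groups and w[0] <= groups[-1][-1][1] + gap:
                groups[-1].append(w)
            else:
                groups.append([w])
        for grp in groups:
            lo = min(w[0] for w in grp)
            hi = max(w[1] for w in grp)
            centers = tuple(sorted(w[2] for w in grp))
            truncated = any(w[3] for w in grp)
            members = tuple(g.gene_id for g in scaffold[lo : hi + 1])
            gn_id = f"{genome.genome_id}:{scaffold_id}:{lo}-{hi}"
            out.append(
                GenomeNeighbourhood(
                    gn_id=gn_id,
                    genome_id=genome.genome_id,
                    scaffold_id=scaffold_id,
                    center_gene_ids=centers,
                    member_gene_ids=members,
                    flank=flank,
                    merged=len(grp) > 1,
                    truncated=truncated,
                    first_rank=lo,
                    last_rank=hi,
                )
            )
    out.sort(key=lambda gn: (gn.scaffold_id, gn.first_rank))
    return out


def filter_by_size(
    gns: Iterable[GenomeNeighbourhood], min_genes: int = 11
) -> list[GenomeNeighbourhood]:
    """Keep GNs with at least ``min_genes`` members, preserving order."""
    kept = [gn for gn in gns if gn.n_genes >= min_genes]
    if not kept:
        logger.warning("filter_by_size(min_genes=%d) removed every GN", min_genes)
    return kept


def classify_bgc(
    gn: GenomeNeighbourhood,
    hits: Iterable[DomainHit],
    enzyme_class_map: Mapping[str, str],
) -> bool:
    """A GN qualifies as a biosynthetic gene cluster when its genes carry
    domains from at least three distinct enzyme classes.

    ``enzyme_class_map`` maps enzymatic domain names (family or subfamily)
    to a class label such as ``scaffold-generating``, ``oxidising`` or
    ``acylating``; non-enzymatic families are simply absent from the map.
    """
    members = set(gn.member_gene_ids)
    classes = set()
    for h in hits:
        if h.gene_id not in members:
            continue
        for name in (h.subfamily, h.family):
            if name and name in enzyme_class_map:
                classes.add(enzyme_class_map[name])
                break
    return len(classes) >= 3


def propagate_clade_labels(
    tree: dendropy.Tree, reference: Sequence[CladeLabel]
) -> list[CladeLabel]:
    """Spread reference clade labels over all leaves of the tree.

    Each unlabeled leaf receives the label of the smallest enclosing clade
    that contains at least one reference leaf, provided all reference
    leaves in that clade agree; if they disagree the leaf is returned with
    ``source="ambiguous"`` (label = ``""``). Reference labels are never
    overwritten. Every leaf appears exactly once in the output.
    """
    ref_by_name = {}
    for cl in reference:
        if cl.leaf_name in ref_by_name and ref_by_name[cl.leaf_name] != cl.label:
            raise ValueError(f"conflicting reference labels for leaf {cl.leaf_name!r}")
        ref_by_name[cl.leaf_name] = cl.label

    leaves = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    missing = set(ref_by_name) - set(leaves)
    if missing:
        raise ValueError(f"reference leaves missing from tree: {sorted(missing)}")

    # labels of reference leaves under each node, computed bottom-up
    under: dict[int, set[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            name = node.taxon.label
            under[id(node)] = {ref_by_name[name]} if name in ref_by_name else set()
        else:
            acc: set[str] = set()
            for child in node.child_nodes():
                acc |= under[id(child)]
            under[id(node)] = acc

    out: list[CladeLabel] = []
    for name in sorted(leaves):
        if name in ref_by_name:
            out.append(CladeLabel(name, ref_by_name[name], "reference"))
            continue
        node = leaves[name].parent_node
        label = None
        ambiguous = False
        while node is not None:
            found = under[id(node)]
            if found:
                if len(found) == 1:
                    label = next(iter(found))
                else:
                    ambiguous = True
                break
            node = node.parent_node
        if label is not None:
            out.append(CladeLabel(name, label, "propagated"))
        else:
            if ambiguous:
                logger.warning("leaf %s has ambiguous clade label", name)
            out.append(CladeLabel(name, "", "ambiguous"))
    return out
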
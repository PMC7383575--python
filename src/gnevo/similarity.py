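"""All-vs-all genome-neighbourhood similarity.

Three complementary indices per GN pair:

* **Jaccard index** of the two domain-name sets — architectural similarity
  of enzyme family content, blind to sequence.
* **Average identity** — mean global-alignment amino-acid identity over
  the optimally matched copies of every shared domain (undefined when the
  pair shares no domain).
* **DSS** (domain sequence similarity) — matched-pair identities summed
  over shared domains, normalised by the total copy number
  ``sum over union families of max(copies_a, copies_b)``, so extra copies
  of a domain present in only one GN, and families absent from one side,
  pull the index down. Self-comparison gives exactly 1.

When the two GNs carry unequal copy numbers of a shared domain, surplus
copies on the larger side are dropped (lowest best-match identity first,
ties by gene id) until the counts agree, and the Hungarian algorithm then
selects the one-to-one pairing maximising total identity.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.optimize import linear_sum_assignment

from .io_formats import AnnotatedGenome, DomainHit, STANDARD_RESIDUES
from .neighbourhoods import GenomeNeighbourhood, filter_by_size

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignmentParams:
    """Global-alignment scoring used for identity computation.

    BLOSUM62 with affine gaps (open 10, extend 0.5) — the field's stock
    parameters for protein-level percent identity. Identity is counted
    over *all* alignment columns, gap columns included.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5


def _make_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def pairwise_identity(
    seq_a: str, seq_b: str, params: AlignmentParams = AlignmentParams()
) -> float:
    """Percent identity of the optimal global alignment of two proteins.

    identity = 100 x identical aligned pairs / alignment columns. The
    first optimal alignment under Biopython's deterministic enumeration is
    used, so results are reproducible. Residues outside the 20 standard
    amino acids (plus X) are replaced by X (scored as near-mismatch) and
    logged.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")

    def clean(seq: str) -> str:
        bad = set(seq.upper()) - STANDARD_RESIDUES
        if bad:
            logger.warning("non-standard residues %s treated as X", sorted(bad))
            return "".join(c if c in STANDARD_RESIDUES else "X" for c in seq.upper())
        return seq.upper()

    aligner = _make_aligner(params)
    alignment = aligner.align(clean(seq_a), clean(seq_b))[0]
    counts = alignment.counts()
    return 100.0 * counts.identities / alignment.length


@dataclass
class DomainCopyProfile:
    """Domain content of one GN, as sequences per domain copy.

    ``copies`` maps each domain name to the ``(gene_id, protein)`` pairs of
    its copies in the GN; genes without a translation are excluded from
    ``copies`` entirely (sequence-based indices ignore them) but their
    domain names still appear in ``families`` for the Jaccard index.
    """

    gn_id: str
    copies: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    families: set[str] = field(default_factory=set)

    @classmethod
    def from_neighbourhood(
        cls,
        gn: GenomeNeighbourhood,
        genome: AnnotatedGenome,
        hits: Iterable[DomainHit] | None = None,
        whitelist: set[str] | None = None,
        level: str = "subfamily",
    ) -> "DomainCopyProfile":
        """Collect the GN's domain copies, optionally restricted to a
        whitelist of specialized-metabolism domain names."""
        hits = genome.hits if hits is None else hits
        members = set(gn.member_gene_ids)
        profile = cls(gn_id=gn.gn_id)
        seen: set[tuple[str, str]] = set()
        for h in hits:
            if h.gene_id not in members:
                continue
            name = h.name_at(level)
            if whitelist is not None and name not in whitelist:
                continue
            key = (h.gene_id, name)
            if key in seen:  # one copy per (gene, domain)
                continue
            seen.add(key)
            profile.families.add(name)
            gene = genome.gene(h.gene_id)
            if gene.protein:
                profile.copies.setdefault(name, []).append((h.gene_id, gene.protein))
        for copies in profile.copies.values():
            copies.sort(key=lambda c: c[0])
        return profile


@dataclass(frozen=True)
class GNPairSimilarity:
    gn_a: str
    gn_b: str
    jaccard: float
    avg_identity: float | None  # percent; None when no shared family
    dss: float
    n_shared_families: int


def optimal_assignment(scores: np.ndarray) -> list[tuple[int, int]]:
    """Row/column pairing of a square score matrix maximising total score."""
    rows, cols = linear_sum_assignment(np.asarray(scores, dtype=float), maximize=True)
    return sorted(zip(rows.tolist(), cols.tolist()))


def trim_surplus(
    scores: np.ndarray, labels: Sequence[str] | None = None
) -> list[int]:
    """Indices of rows to keep so the matrix becomes square.

    ``scores`` has more rows than columns; rows with the lowest best-match
    score are dropped first, ties broken by ``labels`` (gene ids) or row
    index. Returns the kept row indices in original order.
    """
    scores = np.asarray(scores, dtype=float)
    n_drop = scores.shape[0] - scores.shape[1]
    if n_drop <= 0:
        return list(range(scores.shape[0]))
    best = scores.max(axis=1)
    keys = labels if labels is not None else [str(i) for i in range(len(best))]
    order = sorted(range(len(best)), key=lambda i: (best[i], keys[i]))
    dropped = set(order[:n_drop])
    return [i for i in range(scores.shape[0]) if i not in dropped]


def match_domain_copies(
    copies_a: Sequence[tuple[str, str]],
    copies_b: Sequence[tuple[str, str]],
    params: AlignmentParams = AlignmentParams(),
    identity_matrix: np.ndarray | None = None,
) -> list[tuple[int, int, float]]:
    """Optimally pair the copies of one domain across two GNs.

    Returns ``(index_a, index_b, identity_fraction)`` triples,
    ``min(|a|, |b|)`` of them. Surplus copies on the larger side are
    removed lowest-best-identity first (ties by gene id) before the
    Hungarian assignment maximising total identity. ``identity_matrix``
    (fractions, shape ``|a| x |b|``) may be supplied to skip alignment.
    """
    if not copies_a or not copies_b:
        raise ValueError("both copy lists must be non-empty")
    if identity_matrix is None:
        identity_matrix = np.array(
            [
                [pairwise_identity(sa, sb, params) / 100.0 for _, sb in copies_b]
                for _, sa in copies_a
            ]
        )
    M = np.asarray(identity_matrix, dtype=float)
    if M.shape != (len(copies_a), len(copies_b)):
        raise ValueError("identity matrix shape mismatch")

    keep_a = list(range(len(copies_a)))
    keep_b = list(range(len(copies_b)))
    if len(copies_a) > len(copies_b):
        keep_a = trim_surplus(M, [c[0] for c in copies_a])
    elif len(copies_b) > len(copies_a):
        keep_b = trim_surplus(M.T, [c[0] for c in copies_b])
    sub = M[np.ix_(keep_a, keep_b)]
    pairs = optimal_assignment(sub)
    return [(keep_a[i], keep_b[j], float(sub[i, j])) for i, j in pairs]


def jaccard_index(profile_a: DomainCopyProfile, profile_b: DomainCopyProfile) -> float:
    """|families(a) & families(b)| / |families(a) | families(b)|; 0 on empty union."""
    union = profile_a.families | profile_b.families
    if not union:
        logger.warning("jaccard of two empty profiles (%s, %s)", profile_a.gn_id, profile_b.gn_id)
        return 0.0
    return len(profile_a.families & profile_b.families) / len(union)


def compare_profiles(
    profile_a: DomainCopyProfile,
    profile_b: DomainCopyProfile,
    params: AlignmentParams = AlignmentParams(),
) -> GNPairSimilarity:
    """Jaccard, average matched identity and DSS for one GN pair."""
    shared = sorted(set(profile_a.copies) & set(profile_b.copies))
    union = set(profile_a.copies) | set(profile_b.copies)
    numerator = 0.0
    identities: list[float] = []
    for fam in shared:
        for _, _, ident in match_domain_copies(
            profile_a.copies[fam], profile_b.copies[fam], params
        ):
            numerator += ident
            identities.append(ident)
    denominator = sum(
        max(len(profile_a.copies.get(f, ())), len(profile_b.copies.get(f, ())))
        for f in union
    )
    dss = numerator / denominator if denominator else 0.0
    avg_identity = 100.0 * float(np.mean(identities)) if identities else None
    return GNPairSimilarity(
        gn_a=profile_a.gn_id,
        gn_b=profile_b.gn_id,
        jaccard=jaccard_index(profile_a, profile_b),
        avg_identity=avg_identity,
        dss=dss,
        n_shared_families=len(shared),
    )


def dss_index(
    profile_a: DomainCopyProfile,
    profile_b: DomainCopyProfile,
    params: AlignmentParams = AlignmentParams(),
) -> float:
    """Copy-penalised domain sequence similarity in [0, 1]."""
    return compare_profiles(profile_a, profile_b, params).dss


def all_vs_all(
    gns: Sequence[GenomeNeighbourhood],
    genomes: Sequence[AnnotatedGenome],
    whitelist: set[str] | None = None,
    min_genes: int = 11,
    level: str = "subfamily",
    params: AlignmentParams = AlignmentParams(),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """All unordered pairwise comparisons of the size-filtered GNs.

    Returns the per-pair table and the summary bin counts: total pairs,
    pairs sharing no domain, pairs sharing at least one, and — among the
    sharing pairs — those with Jaccard >= 0.5, average identity < 50%, and
    DSS <= 0.3.
    """
    by_genome = {g.genome_id: g for g in genomes}
    kept = filter_by_size(gns, min_genes)
    if len(kept) < 2:
        raise ValueError(f"need >= 2 GNs after size filter, have {len(kept)}")
    profiles = [
        DomainCopyProfile.from_neighbourhood(
            gn, by_genome[gn.genome_id], whitelist=whitelist, level=level
        )
        for gn in kept
    ]
    rows = []
    for pa, pb in itertools.combinations(profiles, 2):
        sim = compare_profiles(pa, pb, params)
        rows.append(
            {
                "gn_a": sim.gn_a,
                "gn_b": sim.gn_b,
                "jaccard": sim.jaccard,
                "avg_identity": sim.avg_identity,
                "dss": sim.dss,
                "n_shared_families": sim.n_shared_families,
            }
        )
    table = pd.DataFrame(
        rows, columns=["gn_a", "gn_b", "jaccard", "avg_identity", "dss", "n_shared_families"]
    )
    shared = table[table["n_shared_families"] > 0]
    summary = {
        "n_gns": len(kept),
        "total_pairs": len(table),
        "pairs_no_shared": int((table["n_shared_families"] == 0).sum()),
        "pairs_shared": len(shared),
        "pairs_jaccard_ge_0.5": int((shared["jaccard"] >= 0.5).sum()),
        "pairs_identity_lt_50": int((shared["avg_identity"] < 50.0).sum()),
        "pairs_dss_le_0.3": int((shared["dss"] <= 0.3).sum()),
    }
    return table, summary


def similarity_matrix(table: pd.DataFrame, value: str = "dss") -> pd.DataFrame:
    """Square symmetric matrix of one pairwise index (self-diagonal = 1)."""
    ids = sorted(set(table["gn_a"]) | set(table["gn_b"]))
    mat = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for _, row in table.iterrows():
        mat.loc[row["gn_a"], row["gn_b"]] = row[value]
        mat.loc[row["gn_b"], row["gn_a"]] = row[value]
    return mat
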
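"""End-to-end orchestration of the neighbourhood-evolution analysis.

``run_pipeline`` drives the stages in order — neighbourhood extraction,
clade-label propagation, domain enrichment (naive and conservative),
all-vs-all similarity, representative-leaf selection, pruning, parsimony
reconstruction and branch-event mapping — writing one TSV per stage, a
run manifest (parameters, seed, config hash) and a summary report whose
bookkeeping identities (``total_pairs = C(n, 2)``,
``shared + no_shared = total``) hold exactly. Reruns with the same
configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import ancestral, enrichment, io_formats, neighbourhoods, similarity

logger = logging.getLogger(__name__)

#: enzyme classes for BGC classification of the stock domain palette
DEFAULT_ENZYME_CLASSES: dict[str, str] = {
    "SQHop_cyclase": "scaffold-generating",
    "SQHop_cyclase_C": "scaffold-generating",
    "SQHop_cyclase_N": "scaffold-generating",
    "p450": "oxidising",
    "CYP705A": "oxidising",
    "CYP708A": "oxidising",
    "CYP702A": "oxidising",
    "CYP716A": "oxidising",
    "Transferase": "acylating",
    "ACT_IIIa": "acylating",
    "ACT_IIIb": "acylating",
    "Methyltransf_32": "methylating",
    "UDPGT": "glycosylating",
}

#: tailoring domains whose gains/losses are reconstructed by default
DEFAULT_TRAIT_DOMAINS = ("CYP705A", "CYP708A", "CYP702A", "ACT_IIIa")


@dataclass
class PipelineConfig:
    """Paths and parameters of one pipeline run.

    Defaults follow the neighbourhood-analysis conventions this package
    implements: flank-5 windows (11-gene GNs), a >= 11-gene size filter
    for the similarity and reconstruction stages, and a Bonferroni
    significance threshold of 0.01.
    """

    genome_paths: list[str] = field(default_factory=list)
    hits_path: str = ""
    tree_path: str = ""
    reference_labels_path: str = ""
    whitelist_path: str | None = None
    flank: int = 5
    min_genes: int = 11
    level: str = "subfamily"
    threshold: float = 0.01
    trait_domains: tuple[str, ...] = DEFAULT_TRAIT_DOMAINS
    enzyme_classes: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_ENZYME_CLASSES)
    )
    alignment: similarity.AlignmentParams = field(default_factory=similarity.AlignmentParams)
    representative_mode: str = "all"
    seed: int = 0
    out_dir: str = "gnevo_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "alignment" in raw:
            raw["alignment"] = similarity.AlignmentParams(**raw["alignment"])
        if "trait_domains" in raw:
            raw["trait_domains"] = tuple(raw["trait_domains"])
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (the output location excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def pair_bookkeeping(
    n_gns_total: int,
    n_excluded_small: int,
    n_pairs_no_shared: int,
    n_bgc: int,
    n_pairs_jaccard_ge_half: int,
) -> dict[str, float]:
    """Combinatorial bookkeeping of an all-vs-all comparison.

    From the stage counts — total GNs in the clade, GNs excluded by the
    size filter, pairs sharing no domain, BGC-qualifying GNs, and
    high-Jaccard pairs — derive the retained-GN pair total
    ``C(n_retained, 2)``, the shared-pair complement and the headline
    percentages. Every derived value recomputes exactly from its inputs.
    """
    n_retained = n_gns_total - n_excluded_small
    total_pairs = math.comb(n_retained, 2)
    if n_pairs_no_shared > total_pairs:
        raise ValueError("more no-shared pairs than pairs")
    pairs_shared = total_pairs - n_pairs_no_shared
    return {
        "n_retained": n_retained,
        "total_pairs": total_pairs,
        "pairs_shared": pairs_shared,
        "pct_bgc": 100.0 * n_bgc / n_gns_total if n_gns_total else float("nan"),
        "pct_jaccard_ge_half": (
            100.0 * n_pairs_jaccard_ge_half / pairs_shared if pairs_shared else float("nan")
        ),
    }


@dataclass
class PipelineResult:
    gns: list[neighbourhoods.GenomeNeighbourhood]
    labels: list[neighbourhoods.CladeLabel]
    gns_by_clade: dict[str, list[neighbourhoods.GenomeNeighbourhood]]
    enrichment_naive: list[enrichment.EnrichmentResult]
    enrichment_conservative: list[enrichment.EnrichmentResult]
    pair_table: pd.DataFrame
    pair_summary: dict[str, int]
    event_maps: list[ancestral.EventMap]
    report: dict


def _load_inputs(config: PipelineConfig):
    genomes = [io_formats.parse_genbank(p) for p in config.genome_paths]
    hits = io_formats.parse_domain_table(config.hits_path)
    for genome in genomes:
        genome.hits = []
        genome.attach_hits([h for h in hits if h.gene_id in genome], strict=True)
    tree = io_formats.parse_newick(config.tree_path)
    ref = pd.read_csv(config.reference_labels_path, sep="\t")
    reference = [
        neighbourhoods.CladeLabel(r.leaf_name, r.label, "reference")
        for r in ref.itertuples()
    ]
    whitelist = None
    if config.whitelist_path:
        whitelist = {
            line.strip()
            for line in Path(config.whitelist_path).read_text(encoding="utf-8").splitlines()
            if line.strip()
        }
    return genomes, tree, reference, whitelist


def run_pipeline(
    config: PipelineConfig, write_outputs: bool = True
) -> PipelineResult:
    """Execute every stage on the configured inputs; see module docstring."""
    stage = "load"
    try:
        genomes, tree, reference, whitelist = _load_inputs(config)
        by_genome = {g.genome_id: g for g in genomes}

        stage = "extract"
        targets = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
        targets_by_genome: dict[str, list[str]] = {}
        for t in targets:
            holders = [g.genome_id for g in genomes if t in g]
            if len(holders) != 1:
                raise ValueError(f"target {t!r} found in {len(holders)} genomes")
            targets_by_genome.setdefault(holders[0], []).append(t)
        gns: list[neighbourhoods.GenomeNeighbourhood] = []
        for genome_id in sorted(targets_by_genome):
            gns.extend(
                neighbourhoods.extract_neighbourhoods(
                    by_genome[genome_id], targets_by_genome[genome_id], config.flank
                )
            )
        center_to_gn = {c: gn for gn in gns for c in gn.center_gene_ids}
        leaf_to_gn = {t: center_to_gn[t].gn_id for t in targets}
        gn_by_id = {gn.gn_id: gn for gn in gns}

        stage = "labels"
        labels = neighbourhoods.propagate_clade_labels(tree, reference)
        clade_of_leaf = {cl.leaf_name: cl.label for cl in labels if cl.label}
        gns_by_clade: dict[str, list[neighbourhoods.GenomeNeighbourhood]] = {}
        duplicated: list[str] = []
        for gn in gns:
            clades = sorted({clade_of_leaf.get(c, "") for c in gn.center_gene_ids} - {""})
            if len(clades) > 1:
                duplicated.append(gn.gn_id)
            for clade in clades:
                gns_by_clade.setdefault(clade, []).append(gn)
        if duplicated:
            logger.warning(
                "%d merged GNs span clades and are attributed to each: %s",
                len(duplicated), duplicated,
            )

        stage = "enrichment"
        kwargs = dict(
            genomes=genomes, gns_by_clade=gns_by_clade, tree=tree,
            leaf_to_gn=leaf_to_gn, level=config.level, threshold=config.threshold,
        )
        enr_naive = enrichment.run_enrichment(mode="naive", **kwargs)
        enr_cons = enrichment.run_enrichment(mode="conservative", **kwargs)

        stage = "similarity"
        pair_table, pair_summary = similarity.all_vs_all(
            gns, genomes, whitelist=whitelist, min_genes=config.min_genes,
            level=config.level, params=config.alignment,
        )
        dss_lookup = {}
        for row in pair_table.itertuples():
            dss_lookup[(row.gn_a, row.gn_b)] = row.dss
            dss_lookup[(row.gn_b, row.gn_a)] = row.dss

        stage = "bgc"
        bgc_flags = {
            gn.gn_id: neighbourhoods.classify_bgc(
                gn, by_genome[gn.genome_id].hits, config.enzyme_classes
            )
            for gn in gns
        }

        stage = "ancestral"
        gn_sizes = {gn.gn_id: gn.n_genes for gn in gns}
        pruned = ancestral.prune_for_reconstruction(
            tree, leaf_to_gn, gn_sizes, config.min_genes
        )
        pruned = ancestral.select_representative_leaves(
            pruned,
            leaf_to_gn,
            lambda a, b: 1.0 if a == b else dss_lookup.get((a, b), 0.0),
            mode=config.representative_mode,
        )
        retained = sorted(leaf.taxon.label for leaf in pruned.leaf_node_iter())
        trait_rows = {}
        for leaf in retained:
            gn = gn_by_id[leaf_to_gn[leaf]]
            genome = by_genome[gn.genome_id]
            members = set(gn.member_gene_ids)
            present = {
                h.name_at(config.level)
                for h in genome.hits
                if h.gene_id in members
            }
            trait_rows[leaf] = {d: int(d in present) for d in config.trait_domains}
        traits = pd.DataFrame.from_dict(trait_rows, orient="index").loc[retained]
        trait_tree = ancestral.TraitTree(
            tree=pruned, traits=traits,
            leaf_to_gn={lf: leaf_to_gn[lf] for lf in retained},
        )
        event_maps = [
            ancestral.map_events(ancestral.fitch_parsimony(trait_tree, d))
            for d in config.trait_domains
        ]

        stage = "report"
        report = _build_report(
            config, gns, gns_by_clade, bgc_flags, enr_naive, enr_cons,
            pair_summary, event_maps, len(retained),
        )
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    result = PipelineResult(
        gns=gns, labels=labels, gns_by_clade=gns_by_clade,
        enrichment_naive=enr_naive, enrichment_conservative=enr_cons,
        pair_table=pair_table, pair_summary=pair_summary,
        event_maps=event_maps, report=report,
    )
    if write_outputs:
        write_pipeline_outputs(config, result, bgc_flags)
    return result


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"pipeline stage {stage!r} failed: {message}")
        self.stage = stage


def _build_report(config, gns, gns_by_clade, bgc_flags, enr_naive, enr_cons,
                  pair_summary, event_maps, n_retained_leaves) -> dict:
    total = pair_summary["total_pairs"]
    assert total == math.comb(pair_summary["n_gns"], 2)
    assert pair_summary["pairs_no_shared"] + pair_summary["pairs_shared"] == total
    sig = lambda results: sorted(
        {(r.clade, r.domain) for r in results if r.significant}
    )
    return {
        "n_gns": len(gns),
        "n_gns_by_clade": {c: len(v) for c, v in sorted(gns_by_clade.items())},
        "n_bgc": sum(bgc_flags.values()),
        "pct_bgc": round(100.0 * sum(bgc_flags.values()) / len(gns), 4) if gns else None,
        "pair_summary": pair_summary,
        "significant_naive": [list(t) for t in sig(enr_naive)],
        "significant_conservative": [list(t) for t in sig(enr_cons)],
        "n_retained_leaves": n_retained_leaves,
        "parsimony": {
            em.domain: {
                "score": em.parsimony_score,
                "gains": em.gains,
                "losses": em.losses,
                "ambiguous_branches": em.n_ambiguous,
            }
            for em in event_maps
        },
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }


def write_pipeline_outputs(
    config: PipelineConfig, result: PipelineResult, bgc_flags: Mapping[str, bool]
) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    gn_rows = [
        {
            "gn_id": gn.gn_id, "genome": gn.genome_id, "scaffold": gn.scaffold_id,
            "n_genes": gn.n_genes, "centers": ",".join(gn.center_gene_ids),
            "merged": gn.merged, "truncated": gn.truncated,
            "is_bgc": bool(bgc_flags[gn.gn_id]),
        }
        for gn in result.gns
    ]
    pd.DataFrame(gn_rows).to_csv(out / "gn_summary.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {"leaf_name": cl.leaf_name, "label": cl.label, "source": cl.source}
            for cl in result.labels
        ]
    ).to_csv(out / "clade_labels.tsv", sep="\t", index=False)

    enrichment.results_to_dataframe(result.enrichment_naive).to_csv(
        out / "enrichment_naive.tsv", sep="\t", index=False
    )
    enrichment.results_to_dataframe(result.enrichment_conservative).to_csv(
        out / "enrichment_conservative.tsv", sep="\t", index=False
    )
    result.pair_table.to_csv(out / "pairs.tsv", sep="\t", index=False)
    pd.DataFrame([result.pair_summary]).to_csv(
        out / "pairs_summary.tsv", sep="\t", index=False
    )
    ancestral.events_to_dataframe(result.event_maps).to_csv(
        out / "events.tsv", sep="\t", index=False
    )
    manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str), encoding="utf-8"
    )
    (out / "report.json").write_text(
        json.dumps(result.report, indent=2, sort_keys=True), encoding="utf-8"
    )
    return out
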
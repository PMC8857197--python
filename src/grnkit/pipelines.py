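"""Named pipeline recipes composing the library modules end to end.

Each recipe reads inputs from disk, runs the corresponding analysis in the
published order, and writes its outputs; all randomness flows from one
top-level seed fanned out per stage, and outputs are written sorted so
re-running a recipe over unchanged inputs is byte-identical.  On stage
failure the partial output is retained with a ``.partial`` suffix and the
failing stage is named.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import yaml

from . import assess, community, core, expression, io, motifs, nda, netstats, synth

logger = logging.getLogger(__name__)

RECIPES = (
    "meta_curate",
    "infer_bs",
    "infer_exp",
    "community_all",
    "assess_all",
    "nda_all",
    "structure_all",
    "regulogs",
)


@dataclass
class PipelineConfig:
    """Per-recipe parameters: input/output paths plus stage options."""

    params: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        return cls(params=raw, seed=int(raw.get("seed", 0)))

    def require(self, *keys: str) -> list[Any]:
        missing = [k for k in keys if k not in self.params]
        if missing:
            raise core.GRNError(f"pipeline config missing keys: {missing}")
        return [self.params[k] for k in keys]


def _outpath(config: PipelineConfig, key: str, default: str) -> Path:
    out_dir = Path(config.params.get("out_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)
    return out_dir / config.params.get(key, default)


def meta_curate(config: PipelineConfig) -> dict[str, Any]:
    """Merge curated networks into a meta-curation and summarize it."""
    (paths,) = config.require("networks")
    nets = [io.read_interactions_tsv(p) for p in paths]
    merged = core.merge_networks(nets, label=config.params.get("label", "meta-curated"))
    out = _outpath(config, "merged_out", "merged.tsv")
    io.write_interactions_tsv(merged, out)
    summary = core.network_summary(merged)
    summary_path = _outpath(config, "summary_out", "merged_summary.json")
    summary_path.write_text(
        json.dumps(
            {
                "genes": summary.genes,
                "interactions": summary.interactions,
                "regulators": summary.regulators,
                "strong_fraction": summary.strong_fraction,
            },
            indent=2,
        )
    )
    return {"merged": str(out), "summary": str(summary_path)}


def infer_bs(config: PipelineConfig) -> dict[str, Any]:
    """Binding-site inference: upstream extraction -> regulon extension."""
    prior_path, genome_path, genes_path = config.require(
        "prior", "genome", "gene_table"
    )
    prior = core.filter_strong(io.read_interactions_tsv(prior_path))
    genome = io.read_fasta(genome_path)
    table = io.read_gene_table(genes_path)
    regions = motifs.extract_upstream(table, genome)
    ranking = motifs.extend_regulons(
        prior,
        regions,
        p_threshold=float(config.params.get("p_threshold", 1e-4)),
        width=int(config.params.get("motif_width", 12)),
    )
    out = _outpath(config, "ranking_out", "inferred_bs.tsv")
    assess.write_ranked_tsv(ranking, out)
    return {"ranking": str(out), "n_predictions": len(ranking)}


def infer_exp(config: PipelineConfig) -> dict[str, Any]:
    """Expression inference with the native MI family (CLR and MRNET)."""
    expr_path, tf_path = config.require("expression", "tf_list")
    expr = expression.load_expression_tsv(expr_path)
    tfs = [
        line.strip()
        for line in Path(tf_path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    mi = expression.mutual_information(
        expr, bins=config.params.get("bins")
    )
    outputs = {}
    for method_name, method in (("clr", expression.clr), ("mrnet", expression.mrnet)):
        if method_name in config.params.get("methods", ["clr", "mrnet"]):
            ranking = method(mi, tfs)
            out = _outpath(config, f"{method_name}_out", f"inferred_{method_name}.tsv")
            assess.write_ranked_tsv(ranking, out)
            outputs[method_name] = str(out)
    return outputs


def community_all(config: PipelineConfig) -> dict[str, Any]:
    """Integrate ranked lists by mean rank and prune to the expected size."""
    (paths,) = config.require("lists")
    lists = [assess.read_ranked_tsv(p) for p in paths]
    integrated = community.integrate(lists)
    k = int(config.params.get("prune", 23908))
    pruned = community.prune_top(integrated, k)
    out = _outpath(config, "community_out", "community.tsv")
    assess.write_ranked_tsv(pruned, out)
    return {"community": str(out), "n_interactions": len(pruned)}


def assess_all(config: PipelineConfig) -> dict[str, Any]:
    """AUPR/AUROC of each ranked list against a gold standard."""
    paths, gold_path = config.require("lists", "gold")
    gold = io.read_interactions_tsv(gold_path)
    results = {}
    for path in paths:
        ranking = assess.restrict_to_gold(assess.read_ranked_tsv(path), gold)
        results[str(path)] = {
            "aupr": assess.pr_curve(ranking, gold).auc,
            "auroc": assess.roc_curve(ranking, gold).auc,
        }
    out = _outpath(config, "assess_out", "assessment.json")
    out.write_text(json.dumps(results, indent=2, sort_keys=True))
    return {"assessment": str(out)}


def nda_all(config: PipelineConfig) -> dict[str, Any]:
    """NDA classification of one or more networks to TSV listings."""
    (paths,) = config.require("networks")
    outputs = {}
    for path in paths:
        net = io.read_interactions_tsv(path)
        strategy = config.params.get("strategy", "elbow")
        fixed = None
        if config.params.get("gr_file"):
            fixed = [
                ln.strip()
                for ln in Path(config.params["gr_file"]).read_text().splitlines()
                if ln.strip()
            ]
        grs = nda.identify_global_regulators(
            net,
            strategy=strategy,
            fixed=fixed,
            min_out_degree=config.params.get("min_out_degree"),
        )
        result = nda.nda_classify(net, grs)
        stem = Path(path).stem
        out = _outpath(config, f"nda_{stem}_out", f"nda_{stem}.tsv")
        with open(out, "w", encoding="utf-8") as handle:
            handle.write("#locus_tag\tclass\tmodule_id\tsubmodule_id\n")
            for tag in sorted(result.class_of):
                mid = result.module_of(tag)
                sid = ""
                if mid is not None:
                    for i, part in enumerate(result.submodules.get(mid, []), 1):
                        if tag in part:
                            sid = f"{mid}.{i}"
                            break
                handle.write(
                    f"{tag}\t{result.class_of[tag].value}\t"
                    f"{mid if mid is not None else ''}\t{sid}\n"
                )
        outputs[str(path)] = str(out)
    return outputs


def structure_all(config: PipelineConfig) -> dict[str, Any]:
    """Structural profiles of networks plus Pearson/Ward clustering."""
    (paths,) = config.require("networks")
    profiles = []
    for path in paths:
        net = io.read_interactions_tsv(path, label=Path(path).stem)
        profiles.append(netstats.structural_profile(net))
    out = _outpath(config, "profiles_out", "profiles.tsv")
    with open(out, "w", encoding="utf-8") as handle:
        handle.write("#property\t" + "\t".join(p.label for p in profiles) + "\n")
        for fname in netstats.PROFILE_FIELDS:
            handle.write(
                fname
                + "\t"
                + "\t".join(f"{getattr(p, fname):.6g}" for p in profiles)
                + "\n"
            )
    outputs = {"profiles": str(out)}
    if len(profiles) >= 2:
        clustering = netstats.cluster_profiles(
            profiles, scaling=config.params.get("scaling", "none")
        )
        tree_out = _outpath(config, "tree_out", "profile_dendrogram.nwk")
        tree_out.write_text(clustering.newick() + "\n")
        outputs["dendrogram"] = str(tree_out)
    return outputs


def regulogs(config: PipelineConfig) -> dict[str, Any]:
    """Cross-species regulon transfer constrained to 1:1 orthologs."""
    src_net, src_genome, src_table, tgt_genome, tgt_table, orth = config.require(
        "source_strong",
        "source_genome",
        "source_gene_table",
        "target_genome",
        "target_gene_table",
        "orthologs",
    )
    source = core.filter_strong(io.read_interactions_tsv(src_net))
    source_regions = motifs.extract_upstream(
        io.read_gene_table(src_table), io.read_fasta(src_genome)
    )
    target_regions = motifs.extract_upstream(
        io.read_gene_table(tgt_table), io.read_fasta(tgt_genome)
    )
    mapping = io.read_ortholog_map(orth)
    target_strong = None
    if config.params.get("target_strong"):
        target_strong = core.filter_strong(
            io.read_interactions_tsv(config.params["target_strong"])
        )
    complemented = motifs.regulogs_transfer(
        source,
        source_regions,
        target_regions,
        mapping,
        p_threshold=float(config.params.get("p_threshold", 1e-4)),
        width=int(config.params.get("motif_width", 12)),
        target_strong=target_strong,
    )
    out = _outpath(config, "complemented_out", "complemented.tsv")
    io.write_interactions_tsv(complemented, out)
    return {"complemented": str(out), "n_interactions": complemented.n_interactions}


_RECIPE_FUNCS: dict[str, Callable[[PipelineConfig], dict[str, Any]]] = {
    "meta_curate": meta_curate,
    "infer_bs": infer_bs,
    "infer_exp": infer_exp,
    "community_all": community_all,
    "assess_all": assess_all,
    "nda_all": nda_all,
    "structure_all": structure_all,
    "regulogs": regulogs,
}


def run_recipe(name: str, config: PipelineConfig) -> dict[str, Any]:
    """Run one named recipe; failures name the stage and keep partials."""
    if name not in _RECIPE_FUNCS:
        raise core.GRNError(f"unknown recipe {name!r}; choose from {RECIPES}")
    logger.info("recipe %s starting (seed=%d)", name, config.seed)
    try:
        outputs = _RECIPE_FUNCS[name](config)
    except Exception as exc:
        out_dir = Path(config.params.get("out_dir", "."))
        for item in out_dir.glob("*.tmp"):
            item.rename(item.with_suffix(".partial"))
        raise core.GRNError(f"recipe {name!r} failed: {exc}") from exc
    logger.info("recipe %s finished: %s", name, outputs)
    return outputs
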
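"""End-to-end orchestration: screen -> reduce -> cluster -> ancestry.

Every stage reads and writes plain TSV under the output directory, so any
stage can be re-run from its persisted inputs and identical config + inputs
give identical outputs. The defaults are the standard gates of this style
of germplasm analysis: D >= 0.50, H >= 0.80, E >= 0.60 for qualitative
diversity; CVbar <= 10% and CV >= 15% for quantitative variation; PCA
eigenvalue >= 0.90 with |loading| >= 0.60; correlation pruning at r > 0.80;
cluster cuts at k = 2 (groups) and k = 5 (subgroups).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import ancestry, clustering, reduction, screening, traitdata
from .traitdata import TraitMatrix

logger = logging.getLogger("phenotax")


@dataclass
class PipelineConfig:
    codebook: str
    observations: str
    register: str
    out_dir: str
    thresholds: screening.ScreeningThresholds = field(
        default_factory=screening.ScreeningThresholds)
    lambda_min: float = 0.90
    load_min: float = 0.60
    r_max: float = 0.80
    preference: list[str] = field(default_factory=list)
    ks: list[int] = field(default_factory=lambda: [2, 5])
    merge_map: dict[int, int] | None = None  # applied to the finest cut
    cluster_codes: dict[int, int] | None = None
    section_codes: dict[str, int] | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        th = raw.pop("thresholds", None)
        cfg = cls(**raw)
        if th:
            cfg.thresholds = screening.ScreeningThresholds(**th)
        return cfg

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunReport:
    trait_counts: dict[str, int]  # candidates -> screened -> pca -> pruned
    partition_sizes: dict[int, dict[int, int]]  # k -> cluster -> size
    ancestry_stats: dict
    config: dict

    def to_json(self) -> str:
        return json.dumps({
            "trait_counts": self.trait_counts,
            "partition_sizes": {
                str(k): {str(c): n for c, n in sizes.items()}
                for k, sizes in self.partition_sizes.items()},
            "ancestry": self.ancestry_stats,
            "config": self.config,
        }, indent=1, default=str)


def run_all(cfg: PipelineConfig) -> RunReport:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cb = traitdata.read_codebook(cfg.codebook)
    reg = traitdata.read_register(cfg.register)
    obs = traitdata.read_observations(cfg.observations)
    traitdata.validate_observations(obs, cb, reg)
    matrix = traitdata.aggregate(obs, cb)
    traitdata.write_matrix(matrix, out / "matrix.tsv")

    # --- stage 1: diversity / variation screening -------------------------
    qual = [t for t in matrix.trait_names if cb.is_qualitative(t)]
    quant = [t for t in matrix.trait_names if not cb.is_qualitative(t)]
    div = screening.compute_diversity(matrix, qual)
    var = screening.compute_variation(obs, matrix, quant)
    kept_qual = screening.screen_qualitative(div, cfg.thresholds)
    kept_quant = screening.screen_quantitative(var, cfg.thresholds)
    screened = kept_qual + kept_quant
    index_table = div.join(var, how="outer")
    index_table["retained"] = [t in screened for t in index_table.index]
    index_table.to_csv(out / "screen_indices.tsv", sep="\t")
    logger.info("screening: %d of %d traits retained",
                len(screened), len(matrix.trait_names))

    # --- stage 2: PCA + correlation pruning -------------------------------
    z = reduction.standardize(matrix.subset(screened))
    pca = reduction.pca_retain(z, cfg.lambda_min)
    pca.to_frame().to_csv(out / "pca.tsv", sep="\t")
    after_pca = reduction.low_contribution_filter(pca, cfg.load_min)
    prune = reduction.correlation_prune(
        matrix, after_pca, cfg.r_max, cfg.preference)
    final_traits = prune.retained
    (out / "traits_final.txt").write_text(
        "\n".join(final_traits) + "\n", encoding="utf-8")
    pd.DataFrame(prune.pairs, columns=["trait_a", "trait_b", "r"]).to_csv(
        out / "prune_pairs.tsv", sep="\t", index=False)

    counts = {
        "candidates": len(matrix.trait_names),
        "after_screen": len(screened),
        "after_pca": len(after_pca),
        "after_prune": len(final_traits),
    }
    assert (counts["candidates"] >= counts["after_screen"]
            >= counts["after_pca"] >= counts["after_prune"])

    # --- stage 3: clustering ---------------------------------------------
    zfinal = reduction.standardize(matrix.subset(final_traits))
    dist = clustering.euclidean_distances(zfinal)
    dendro = clustering.ward_d2(dist)
    pd.DataFrame(dendro.linkage,
                 columns=["node_a", "node_b", "height", "size"]).to_csv(
        out / "merges.tsv", sep="\t", index=False)
    (out / "dendrogram.nwk").write_text(dendro.to_newick() + "\n",
                                        encoding="utf-8")
    partitions: dict[int, clustering.Partition] = {}
    sizes: dict[int, dict[int, int]] = {}
    for k in cfg.ks:
        part = clustering.cut(dendro, k, level=f"k{k}")
        partitions[k] = part
        sizes[k] = part.sizes()
        pd.Series(part.assignments, name="cluster").rename_axis(
            "germplasm_id").to_csv(out / f"partition_k{k}.tsv", sep="\t")
        summary = clustering.summarize_groups(part, matrix, reg)
        summary.counts.to_csv(out / f"groups_k{k}_counts.tsv", sep="\t")
        if not summary.quantitative.empty:
            summary.quantitative.to_csv(out / f"groups_k{k}_quant.tsv", sep="\t")

    # --- stage 4: ancestry ------------------------------------------------
    anc: dict = {}
    ped = ancestry.PedigreeSet.from_register(reg)
    fine = partitions[max(cfg.ks)]
    if len(ped) > 0:
        for k, part in partitions.items():
            anc[f"ancestor_inclined_pct_k{k}"] = (
                ancestry.ancestor_inclined_probability(ped, part))
        freqs, unknown = ancestry.breeding_frequency(ped)
        anc["breeding_frequency_pct"] = dict(
            sorted(freqs.items(), key=lambda kv: (-kv[1], kv[0])))
        anc["unknown_slot_pct"] = unknown
    if any(r.section for r in reg.records):
        sec = ancestry.section_distribution(fine, reg)
        sec.to_csv(out / "section_distribution.tsv", sep="\t")
        anc["species_proportions_pct"] = clustering.species_proportions(fine, reg)
        anc["species_share_pct"] = clustering.species_share(fine, reg)
    part_for_order = fine
    if cfg.merge_map:
        part_for_order = ancestry.merge_clusters(fine, cfg.merge_map)
    if cfg.cluster_codes and cfg.section_codes:
        coding = ancestry.OrderCoding(
            tuple(cfg.cluster_codes.items()), tuple(cfg.section_codes.items()))
        oc = ancestry.order_correlation(coding, part_for_order, reg)
        anc["order_correlation"] = {
            "r": oc.r, "r2": oc.r2, "p_value": oc.p_value, "n": oc.n}

    report = RunReport(trait_counts=counts, partition_sizes=sizes,
                       ancestry_stats=anc, config=cfg.echo())
    (out / "report.json").write_text(report.to_json() + "\n", encoding="utf-8")
    return report
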
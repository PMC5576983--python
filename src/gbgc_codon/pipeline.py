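"""End-to-end analysis pipeline.

Chains every stage of the analysis over one dataset (in-memory synthetic
bundle or a directory of standard files): per-gene codon-usage features,
intragenic crossover rates, meiotic expression, gene-set filtering and
categories, RSCU PCA, the isoacceptor selection test, expression-decile
rate contrasts, stratified metagene profiles, the per-sample GC3~expression
ranking and the sequential variance partition of GC3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import expression as expr_mod
from . import gene_sets as gs
from . import recombination as rec
from . import stats as st
from .isoacceptor import HUMAN_PARTITION, SelectionTestResult, selection_test
from .sequence_features import (
    codon_counts,
    concat_usage,
    gc3,
    gene_features,
    load_gene_models,
    read_fasta,
    rscu,
)
from .synthetic import SyntheticDataset

logger = logging.getLogger(__name__)

#: pseudocount for putting crossover rates on a log scale (cM/Mb)
RATE_PSEUDOCOUNT = 0.01


@dataclass
class PipelineResult:
    features: pd.DataFrame  # per-gene gc3, gci, gc_flank, n_codons, rate, category, expr
    set_rscu: pd.DataFrame  # sets × 59 codons
    set_gc3: pd.Series
    pca: st.RSCUPCA
    pc1_gc3_r2: float
    isoacceptor: SelectionTestResult
    decile: rec.DecileContrast
    metagene: dict[int, rec.MetageneProfile]
    anova: st.SequentialANOVA
    sample_ranking: pd.DataFrame
    category_tests: st.GroupTestReport


def load_dataset_dir(path) -> SyntheticDataset:
    """Rehydrate a dataset from the files `SyntheticDataset.write` emits."""
    from .gene_sets import GeneSetCollection
    from .synthetic import SyntheticConfig

    p = Path(path)
    genome = read_fasta(p / "genome.fa") if (p / "genome.fa").exists() else None
    cds = read_fasta(p / "cds.fa") if (p / "cds.fa").exists() else None
    models = load_gene_models(p / "genes.gff3", genome)
    gmap = rec.GeneticMap.read_tsv(p / "genetic_map.tsv")
    base = (
        rec.GeneticMap.read_tsv(p / "genetic_map_base.tsv")
        if (p / "genetic_map_base.tsv").exists()
        else gmap
    )
    truth = pd.read_csv(p / "truth.tsv", sep="\t", index_col=0)
    return SyntheticDataset(
        config=SyntheticConfig(),
        models=models,
        base_map=base,
        genetic_map=gmap,
        hotspots=rec.read_hotspots_bed(p / "hotspots.bed"),
        expression=expr_mod.read_expression_tsv(p / "expression.tsv"),
        sample_metadata=pd.read_csv(p / "sample_metadata.tsv", sep="\t"),
        sets=GeneSetCollection.read_gmt(p / "gene_sets.gmt"),
        set_names=_gmt_descriptions(p / "gene_sets.gmt"),
        truth=truth,
        genome=genome,
        cds=cds,
    )


def _gmt_descriptions(path) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 2:
                out[fields[0]] = fields[1]
    return out


def run_pipeline(
    dataset: SyntheticDataset,
    *,
    min_gene_length: int = 5_000,
    min_set_size: int = 40,
    flank_width: int = 10_000,
    n_expression_bins: int = 10,
    metagene_span: int = 5_000,
) -> PipelineResult:
    """Run the full analysis on one dataset."""
    models = gs.length_filter(dataset.models, min_len=min_gene_length)
    by_id = {m.gene_id: m for m in models}
    logger.info("length filter: %d of %d genes kept", len(models), len(dataset.models))

    # per-gene codon tables and composition features
    if dataset.cds is None:
        raise ValueError("pipeline needs CDS sequences (run simulate with sequences)")
    tables = {
        gid: codon_counts(seq, source=gid)
        for gid, seq in dataset.cds.items()
        if gid in by_id
    }
    if dataset.genome is not None:
        feats = gene_features(
            models, dataset.genome, cds_seqs=dataset.cds, flank_width=flank_width
        )
    else:
        feats = pd.DataFrame(
            {
                "gc3": {g: gc3(t) for g, t in tables.items()},
                "gci": np.nan,
                "gc_flank": np.nan,
                "n_codons": {g: t.n_codons_total for g, t in tables.items()},
            }
        ).rename_axis("gene_id")

    # intragenic crossover rates and meiotic expression
    rates = rec.interval_rates(dataset.genetic_map, models)
    grouped = expr_mod.average_replicates(dataset.expression, dataset.sample_metadata)
    meiotic = expr_mod.meiotic_sex_average(grouped, "female_meiotic", "male_meiotic")
    feats = feats.join(rates["rate_cM_per_Mb"]).join(
        meiotic.sex_averaged.rename("meiotic_fpkm")
    )
    feats["log_rate"] = expr_mod.log_transform(
        feats["rate_cM_per_Mb"], pseudocount=RATE_PSEUDOCOUNT
    )
    feats["log_expression"] = expr_mod.log_transform(feats["meiotic_fpkm"])

    # gene sets, categories
    sets = gs.filter_sets(
        gs.restrict_to_universe(dataset.sets, feats.index), min_size=min_set_size
    )
    categories = gs.assign_categories(sets, set_names=dataset.set_names)
    feats["category"] = categories.reindex(feats.index).fillna("other")

    # per-set concatenated usage, RSCU matrix, PCA
    set_tables = {
        name: concat_usage(sorted(members), tables, source=name)
        for name, members in sets.sets.items()
    }
    set_rscu = pd.DataFrame({name: rscu(t) for name, t in set_tables.items()}).T
    set_gc3 = pd.Series({name: gc3(t) for name, t in set_tables.items()}, name="gc3")
    pca = st.RSCUPCA(n_components=2).fit(set_rscu, gc3=set_gc3)
    pc1_r2 = st.pairwise_r2(pca.coordinates_["PC1"], set_gc3).r_squared

    # isoacceptor selection test
    iso = selection_test(set_tables, HUMAN_PARTITION)

    # expression-decile contrast of intragenic rate, metagene profiles
    usable = feats.dropna(subset=["rate_cM_per_Mb", "meiotic_fpkm"])
    decile = rec.decile_contrast(
        usable["rate_cM_per_Mb"], usable["meiotic_fpkm"], k=n_expression_bins
    )
    metagene = rec.stratified_metagene_profiles(
        dataset.genetic_map,
        [by_id[g] for g in usable.index],
        usable["meiotic_fpkm"],
        n_strata=3,
        span=metagene_span,
    )

    # sequential variance partition of GC3
    predictors = [p for p in ("gci", "gc_flank", "log_rate", "log_expression")
                  if feats[p].notna().any()]
    anova_cat = "category" if feats["category"].nunique() > 1 else None
    anova = st.SequentialANOVA().fit(feats, "gc3", predictors, category=anova_cat)

    ranking = st.sample_correlation_ranking(feats["gc3"], grouped.loc[feats.index])
    cat_mask = feats["category"].isin(["proliferation", "differentiation", "other"])
    cat_tests = st.group_tests(
        feats.loc[cat_mask, "gc3"], feats.loc[cat_mask, "category"]
    )

    return PipelineResult(
        features=feats,
        set_rscu=set_rscu,
        set_gc3=set_gc3,
        pca=pca,
        pc1_gc3_r2=float(pc1_r2),
        isoacceptor=iso,
        decile=decile,
        metagene=metagene,
        anova=anova,
        sample_ranking=ranking,
        category_tests=cat_tests,
    )


def write_results(result: PipelineResult, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.features.to_csv(out / "gene_features.tsv", sep="\t", na_rep="NA")
    result.set_rscu.to_csv(out / "set_rscu.tsv", sep="\t", na_rep="NA")
    result.pca.coordinates_.join(result.set_gc3).to_csv(
        out / "set_pca.tsv", sep="\t"
    )
    result.isoacceptor.per_set.to_csv(out / "isoacceptor_gc3.tsv", sep="\t")
    result.anova.partition_.to_csv(out / "variance_partition.tsv", sep="\t", index=False)
    result.sample_ranking.to_csv(out / "sample_ranking.tsv", sep="\t", index=False)
    result.decile.per_bin.to_csv(out / "expression_decile_rates.tsv", sep="\t")
    for stratum, prof in result.metagene.items():
        prof.frame.to_csv(
            out / f"metagene_tss_tercile{stratum}.tsv", sep="\t", index=False
        )
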
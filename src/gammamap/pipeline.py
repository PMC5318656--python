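"""End-to-end orchestration of the damage-hotspot analysis on one config.

Stage order mirrors the analysis narrative: simulate inputs, call regions
per condition, merge the condition lists, annotate against the gene models,
meta-gene profiling, expression and active-chromatin integration,
orientation classes, RLFS scanning, and the enrichment statistics. Every
stage logs its outputs into a manifest; a failure aborts with the stage
name and writes the partial manifest.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from . import annotate as ann
from . import expression as expr
from . import io as gio
from . import orientation as orient
from . import regions as reg
from . import rlfs as rl
from . import stats as st
from .config import PipelineConfig
from .simulate import GenomeSpec, simulate_study, write_fixture

logger = logging.getLogger(__name__)

__all__ = ["StageError", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def _df_to_tsv(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return str(path)


def run_pipeline(config: PipelineConfig) -> Dict:
    """Run every stage on the configured synthetic study; return results.

    Deterministic given the config (all randomness flows from config.seed);
    writes tabular outputs plus ``manifest.json`` under config.outdir.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: Dict = dict(version=__version__, parameters=config.to_dict(),
                          stages={})
    results: Dict = {}

    def finish_stage(name: str, outputs: Dict[str, str]) -> None:
        manifest["stages"][name] = outputs
        logger.info("stage %s done: %s", name, sorted(outputs))

    def fail(name: str, exc: BaseException):
        gio.write_json(manifest, outdir / "manifest.json")
        raise StageError(name, exc) from exc

    # -- simulate -----------------------------------------------------------
    try:
        spec = GenomeSpec(chrom_sizes=config.chrom_sizes,
                          gc_background=config.gc_background,
                          seed=config.seed)
        study = simulate_study(spec=spec, n_genes=config.n_genes,
                               n_reads=config.n_reads,
                               enrichment=config.enrichment,
                               expression_coef=config.expression_coef,
                               length_range=(config.gene_length_min,
                                             config.gene_length_max),
                               max_dist=config.max_dist,
                               n_hotspot=config.n_hotspot,
                               seed=config.seed,
                               with_sequence=config.with_sequence,
                               with_h3k27ac=config.with_h3k27ac)
        paths = write_fixture(study, outdir / "inputs")
        finish_stage("simulate", paths)
    except StageError:
        raise
    except Exception as exc:
        fail("simulate", exc)

    genes = [g.to_gene_model() for g in study.genes]
    chrom_sizes = dict(spec.chrom_sizes)
    params = reg.IslandParams(window=config.window, gap=config.gap,
                              p0=config.p0, fc_min=config.fc_min,
                              fdr_max=config.fdr_max, pseudo=config.pseudo)
    ctrl_lib = study.libraries["control"]
    ctrl_track = reg.bin_tags(ctrl_lib, config.window, chrom_sizes)

    # -- region calling per condition --------------------------------------
    called: Dict[str, List[reg.GammaRegion]] = {}
    for cond in ("A", "B"):
        stage = f"call_{cond}"
        try:
            chip = study.libraries[f"chip_{cond}"]
            track = reg.bin_tags(chip, config.window, chrom_sizes)
            islands = reg.call_islands(track, ctrl_track, params, origin=cond)
            called[cond] = islands
            p = outdir / f"regions_{cond}.bed"
            gio.write_regions_bed(islands, p)
            finish_stage(stage, {"regions": str(p)})
        except Exception as exc:
            fail(stage, exc)

    # -- merge --------------------------------------------------------------
    try:
        merged = reg.merge_region_lists(called["A"], called["B"])
        rows = []
        for m in merged:
            _, _, nrpm_a, fc_a, _ = reg.normalize_region(
                m.interval, study.libraries["chip_A"], ctrl_lib, config.pseudo)
            _, _, nrpm_b, fc_b, _ = reg.normalize_region(
                m.interval, study.libraries["chip_B"], ctrl_lib, config.pseudo)
            rows.append(dict(chrom=m.interval.chrom, start=m.interval.start,
                             end=m.interval.end,
                             origin=",".join(sorted(m.origin)),
                             common=m.is_common, nrpm_A=nrpm_a, fc_A=fc_a,
                             nrpm_B=nrpm_b, fc_B=fc_b))
        merged_df = pd.DataFrame(rows)
        p = _df_to_tsv(merged_df, outdir / "regions_merged.tsv")
        specific = reg.condition_specific_regions(
            called["A"], study.libraries["chip_A"], study.libraries["chip_B"],
            ctrl_lib, min_fc_ab=config.min_fc_ab, eps=config.specific_eps)
        p2 = _df_to_tsv(specific, outdir / "regions_specific_A.tsv")
        results["merged"] = merged
        results["specific_A"] = specific
        finish_stage("merge", {"merged": p, "specific_A": p2})
    except StageError:
        raise
    except Exception as exc:
        fail("merge", exc)

    # -- annotate -----------------------------------------------------------
    try:
        assign = ann.assign_genes(merged, genes, flank=config.flank,
                                  chrom_sizes=chrom_sizes)
        gene_rows = []
        for m, glist in zip(merged, assign.region_genes):
            for gid in glist:
                gene_rows.append(dict(chrom=m.interval.chrom,
                                      start=m.interval.start,
                                      end=m.interval.end, gene_id=gid))
        p = _df_to_tsv(pd.DataFrame(gene_rows),
                       outdir / "region_gene_map.tsv")
        rank = reg.rank_regions(called["A"],
                                ann.assign_genes(called["A"], genes,
                                                 flank=config.flank,
                                                 chrom_sizes=chrom_sizes
                                                 ).region_genes)
        p2 = _df_to_tsv(rank, outdir / "region_ranking_A.tsv")
        results["assignment"] = assign
        results["ranking_A"] = rank
        finish_stage("annotate", {
            "region_gene_map": p, "ranking_A": p2,
            "summary": json.dumps(dict(
                n_regions_zero=assign.n_regions_zero,
                n_regions_one=assign.n_regions_one,
                n_regions_multi=assign.n_regions_multi,
                n_distinct_genes=assign.n_distinct_genes))})
    except StageError:
        raise
    except Exception as exc:
        fail("annotate", exc)

    # -- metagene + chromosome coverage -------------------------------------
    try:
        profile = ann.metagene_profile(
            study.libraries["chip_A"], ctrl_lib, genes,
            n_body_bins=config.n_body_bins, flank_bp=config.flank,
            flank_bin_bp=config.flank_bin_bp, mode=config.metagene_mode,
            chrom_sizes=chrom_sizes)
        p = _df_to_tsv(profile.as_frame(), outdir / "metagene.tsv")
        cov_table, cov_r, cov_slope, cov_icpt = None, float("nan"), \
            float("nan"), float("nan")
        if len(chrom_sizes) >= 3:
            cov_table, cov_r, cov_slope, cov_icpt = ann.chrom_coverage_stats(
                merged, genes)
            _df_to_tsv(cov_table, outdir / "chrom_coverage.tsv")
        else:
            cov_table, _, _, _ = ann.chrom_coverage_stats(merged, genes) \
                if len(chrom_sizes) >= 2 else (pd.DataFrame(), cov_r,
                                               cov_slope, cov_icpt)
            if len(cov_table):
                _df_to_tsv(cov_table, outdir / "chrom_coverage.tsv")
        results["metagene"] = profile
        results["chrom_coverage"] = dict(r=cov_r, slope=cov_slope,
                                         intercept=cov_icpt)
        finish_stage("metagene", {"profile": str(p)})
    except StageError:
        raise
    except Exception as exc:
        fail("metagene", exc)

    # -- expression integration ---------------------------------------------
    try:
        cats = expr.categorize_expression(study.expression, condition="A",
                                          expressed_min=config.expressed_min)
        sig_a = expr.gene_signal(genes, study.libraries["chip_A"], ctrl_lib,
                                 flank=config.flank, chrom_sizes=chrom_sizes)
        sig_b = expr.gene_signal(genes, study.libraries["chip_B"], ctrl_lib,
                                 flank=config.flank, chrom_sizes=chrom_sizes)
        cat_test = expr.category_signal_test(sig_a, cats)
        de = expr.differential_expression(study.expression,
                                          min_abs_log2fc=config.min_abs_log2fc,
                                          expressed_min=config.expressed_min,
                                          delta=config.de_delta)
        r, slope, icpt, delta_tab = expr.delta_signal_correlation(sig_a, sig_b,
                                                                  de)
        out = {"categories": _df_to_tsv(cats, outdir / "expression_categories.tsv"),
               "gene_signal": _df_to_tsv(
                   pd.DataFrame({"gene_id": sig_a.index, "nrpm_A": sig_a.values,
                                 "nrpm_B": sig_b.reindex(sig_a.index).values}),
                   outdir / "gene_signal.tsv"),
               "de": _df_to_tsv(de, outdir / "differential_expression.tsv")}
        results["category_test"] = cat_test
        results["delta_correlation"] = dict(r=r, slope=slope, intercept=icpt)
        results["gene_signal_A"] = sig_a
        results["gene_signal_B"] = sig_b
        results["categories"] = cats
        if "h3k27ac" in study.libraries:
            k27 = expr.h3k27ac_gamma_correlation(
                merged, study.libraries["chip_A"], study.libraries["h3k27ac"],
                ctrl_lib, flank=config.flank, chrom_sizes=chrom_sizes)
            results["h3k27ac"] = k27
        summary = dict(category_test=cat_test,
                       delta_correlation=results["delta_correlation"],
                       h3k27ac=results.get("h3k27ac"))
        gio.write_json(summary, outdir / "expression_summary.json")
        out["summary"] = str(outdir / "expression_summary.json")
        finish_stage("expression", out)
    except StageError:
        raise
    except Exception as exc:
        fail("expression", exc)

    # -- orientation ---------------------------------------------------------
    try:
        classes = orient.classify_gene_pairs(genes, max_dist=config.max_dist)
        class_df = pd.DataFrame([dict(gene_id=c.gene_id, category=c.category,
                                      partner=c.partner_id or ".",
                                      gap_bp=c.gap_bp) for c in classes])
        p = _df_to_tsv(class_df, outdir / "orientation_classes.tsv")
        prof = orient.category_fc_profiles(
            genes, classes, study.libraries["chip_A"], ctrl_lib,
            n_bins=config.orientation_bins, eps=config.orientation_eps)
        gio.write_json(prof["tests"], outdir / "orientation_tests.json")
        results["orientation"] = prof
        results["orientation_classes"] = classes
        finish_stage("orientation", {
            "classes": p, "tests": str(outdir / "orientation_tests.json")})
    except StageError:
        raise
    except Exception as exc:
        fail("orientation", exc)

    # -- RLFS ----------------------------------------------------------------
    try:
        if study.sequences:
            matches = []
            for chrom, seq in study.sequences.items():
                matches.extend(rl.find_rlfs_both_strands(seq, chrom=chrom))
            counts = rl.count_rlfs_per_gene(matches, genes)
            match_df = pd.DataFrame([
                dict(chrom=m.interval.chrom, start=m.interval.start,
                     end=m.interval.end, model=m.model_id, strand=m.strand,
                     riz_g=m.riz_g_fraction, rez_g=m.rez_g_fraction)
                for m in matches])
            p = _df_to_tsv(match_df, outdir / "rlfs_matches.tsv")
            p2 = _df_to_tsv(pd.DataFrame(
                {"gene_id": list(counts), "rlfs_count": list(counts.values())}),
                outdir / "rlfs_per_gene.tsv")
            results["rlfs_counts"] = counts
            results["rlfs_matches"] = matches
            finish_stage("rlfs", {"matches": p, "per_gene": p2})
        else:
            results["rlfs_counts"] = {}
            finish_stage("rlfs", {})
    except StageError:
        raise
    except Exception as exc:
        fail("rlfs", exc)

    # -- enrichment statistics ----------------------------------------------
    try:
        enrich: Dict = {}
        gamma_genes = results["assignment"].gene_ids
        population = [g.gene_id for g in genes]
        if results["rlfs_counts"] and gamma_genes:
            perm = st.permute_gene_sample(results["rlfs_counts"], gamma_genes,
                                          population, n_perm=config.n_perm,
                                          seed=config.seed + 1)
            enrich["rlfs_all_genes"] = dict(observed=perm.observed,
                                            null_mean=perm.null_mean,
                                            null_sd=perm.null_sd,
                                            p=perm.empirical_p)
            fpkm = study.expression.set_index("gene_id")["fpkm_A"]
            top = fpkm.sort_values(ascending=False) \
                .head(config.top_expressed).index.tolist()
            if set(gamma_genes) & set(top):
                perm_top = st.permute_gene_sample(
                    results["rlfs_counts"], gamma_genes, population,
                    n_perm=config.n_perm, seed=config.seed + 2,
                    restrict_to=top)
                enrich["rlfs_top_expressed"] = dict(
                    observed=perm_top.observed, null_mean=perm_top.null_mean,
                    null_sd=perm_top.null_sd, p=perm_top.empirical_p)
        if called["A"] and called["B"]:
            ov = st.permute_region_overlap(called["A"], called["B"],
                                           chrom_sizes, n_perm=config.n_perm,
                                           seed=config.seed + 3,
                                           strategy=config.overlap_strategy)
            enrich["region_overlap_A_vs_B"] = dict(
                targets_hit=ov.targets_hit.observed,
                p=ov.targets_hit.empirical_p,
                pct_targets=ov.pct_targets_overlapping,
                pct_queries=ov.pct_queries_overlapping)
        lymphoid = [g.gene_id for g in study.genes
                    if g.lineage_tag == "lymphoid"]
        if gamma_genes and lymphoid:
            overlap = len(set(gamma_genes) & set(lymphoid))
            cont = st.contingency_enrichment(overlap, len(gamma_genes),
                                             len(lymphoid), len(population))
            enrich["lymphoid_contingency"] = dict(
                table=cont.table, odds_ratio=cont.odds_ratio, p=cont.p_value)
        gio.write_json(enrich, outdir / "enrichment.json")
        results["enrichment"] = enrich
        finish_stage("enrichment", {"summary": str(outdir / "enrichment.json")})
    except StageError:
        raise
    except Exception as exc:
        fail("enrichment", exc)

    gio.write_json(manifest, outdir / "manifest.json")
    results["manifest"] = manifest
    results["called"] = called
    results["study"] = study
    return results
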
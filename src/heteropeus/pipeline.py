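"""End-to-end orchestration: filter -> annotate -> score -> heterosis -> correlate.

`run_pipeline` drives the whole analysis from files (VCF + GFF3 + design
CSV + plot CSV) to a report directory of stage TSVs plus a markdown
summary. `replicate_predictor_comparison` runs one fully in-memory
simulated replicate and returns the predictor correlations — the
workhorse of the recovery experiments.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import association, heterosis, scoring
from .annotation import annotate_matrix, build_region_index, read_gff3, write_peus_bed
from .genotype_io import FilterConfig, filter_variants, read_vcf
from .simulate import SimulationConfig, full_experiment

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    vcf: str
    gff: str
    design: str
    plots: str
    outdir: str
    filter: FilterConfig = field(default_factory=FilterConfig)
    promoter_len: int = 1000
    scope: str = "across"  # heterosis scope for the headline tables
    top_k: int = 10
    alpha: float = 0.05


def run_pipeline(cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run every stage, writing TSVs and a markdown report to cfg.outdir.

    Returns the in-memory stage tables keyed by stage name. Any stage
    failure aborts with the stage name attached to the exception.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, pd.DataFrame] = {}
    stage = "setup"
    try:
        stage = "filter"
        t0 = time.perf_counter()
        gm = filter_variants(read_vcf(cfg.vcf), cfg.filter)
        logger.info("[%s] %d samples x %d sites (%.2fs)", stage, gm.n_samples, gm.n_sites,
                     time.perf_counter() - t0)

        stage = "annotate"
        t0 = time.perf_counter()
        idx = build_region_index(read_gff3(cfg.gff), cfg.promoter_len)
        ann = annotate_matrix(gm, idx)
        write_peus_bed(idx, str(out / "peus_regions.bed"))
        counts = ann.category_counts()
        counts_df = pd.DataFrame(
            {"category": list(counts), "n_sites": list(counts.values())}
        )
        counts_df.loc[len(counts_df)] = ["ANY_PEUS", ann.n_peus]
        counts_df.to_csv(out / "peus_counts.tsv", sep="\t", index=False)
        results["peus_counts"] = counts_df
        logger.info("[%s] %d / %d PEUS sites (%.2fs)", stage, ann.n_peus, gm.n_sites,
                     time.perf_counter() - t0)

        stage = "score"
        design = scoring.read_design_csv(cfg.design)
        scores = scoring.score_all(gm, ann, design)
        scores.to_csv(out / "scores.tsv", sep="\t", index=False)
        results["scores"] = scores
        for by in ("tester", "line", "group"):
            agg = scoring.aggregate_by_parent(scores, by=by, design=design)
            agg.to_csv(out / f"scores_by_{by}.tsv", sep="\t", index=False)
            results[f"scores_by_{by}"] = agg
        logger.info("[%s] %d crosses scored", stage, len(scores))

        stage = "heterosis"
        plots = heterosis.read_plots_csv(cfg.plots)
        het = heterosis.compute_heterosis(plots, design, scope=cfg.scope)
        het_loc = heterosis.compute_heterosis(plots, design, scope="per-location")
        anova = heterosis.anova_line_tester(plots, design)
        ca = heterosis.combining_ability(plots, design)
        het.to_csv(out / "heterosis.tsv", sep="\t", index=False)
        het_loc.to_csv(out / "heterosis_per_location.tsv", sep="\t", index=False)
        anova.to_csv(out / "anova.tsv", sep="\t", index=False)
        ca.sca.to_csv(out / "sca.tsv", sep="\t")
        results.update({"heterosis": het, "heterosis_per_location": het_loc, "anova": anova})
        logger.info("[%s] ANOVA over %d plots", stage, len(plots))

        stage = "correlate"
        per_loc = association.predictor_correlations_per_location(scores, het_loc)
        comparison = association.compare_predictors_across_locations(per_loc)
        per_loc.to_csv(out / "correlations_per_location.tsv", sep="\t", index=False)
        results["correlations_per_location"] = per_loc

        merged = het.merge(scores[["cross", "n_het_peus", "gd"]], on="cross")
        summary_rows = []
        for by, frame_key in (("tester", "male"), ("line", "female")):
            agg_scores = scoring.aggregate_by_parent(scores, by=by, design=design)
            agg_het = merged.groupby(frame_key)[["mph", "bph"]].mean().reset_index()
            tbl = agg_scores.merge(agg_het, left_on=by, right_on=frame_key)
            for response in ("mph", "bph"):
                res = association.pearson(tbl["n_het_peus"], tbl[response])
                reg = association.regress(tbl["n_het_peus"], tbl[response])
                summary_rows.append(
                    {"grouping": by, "response": response, "r": res.r, "n": res.n,
                     "p_value": res.p_value, "r_squared": reg.r_squared}
                )
        agg_corr = pd.DataFrame(summary_rows)
        agg_corr.to_csv(out / "correlations_aggregated.tsv", sep="\t", index=False)
        results["correlations_aggregated"] = agg_corr

        f1_means = merged[["cross", "female", "male", "f1_mean"]].rename(columns={"f1_mean": "gy"})
        top, parent_counts = association.top_crosses(f1_means, k=min(cfg.top_k, len(f1_means)))
        parent_counts.to_csv(out / "top_cross_parents.tsv", sep="\t", index=False)
        results["top_cross_parents"] = parent_counts

        stage = "report"
        _write_report(out, results, comparison, cfg)
    except Exception as e:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {e}") from e
    return results


def _write_report(out: Path, results, comparison, cfg: PipelineConfig) -> None:
    lines = ["# heteropeus pipeline report", ""]
    lines += ["## ANOVA (grain yield, line x tester)", "",
              results["anova"].to_markdown(index=False), ""]
    lines += ["## PEUS site counts", "", results["peus_counts"].to_markdown(index=False), ""]
    lines += ["## Aggregated predictor correlations", "",
              results["correlations_aggregated"].to_markdown(index=False), ""]
    lines += ["## Per-location predictor correlations", "",
              results["correlations_per_location"].to_markdown(index=False), "",
              f"Paired comparison (Fisher-z): t = {comparison.t_statistic:.3f}, "
              f"p = {comparison.p_value:.4f}", ""]
    lines += [f"## Parents of the top-{cfg.top_k} crosses by yield", "",
              results["top_cross_parents"].to_markdown(index=False), ""]
    (out / "report.md").write_text("\n".join(lines))


def replicate_predictor_comparison(cfg: SimulationConfig, seed: int) -> dict[str, float]:
    """One simulated replicate: correlations of both predictors with MPH.

    Simulates the panel, trial and phenotypes at the given seed, runs the
    scoring and heterosis stages in memory, and returns r(n_het_peus, MPH)
    and r(GD, MPH) over the simulated crosses (across-location scope).
    """
    bundle = full_experiment(cfg, seed=seed)
    scores = scoring.score_all(bundle.gm, bundle.annotation, bundle.design)
    het = heterosis.compute_heterosis(bundle.plots, bundle.design, scope="across")
    merged = het.merge(scores[["cross", "n_het_peus", "gd"]], on="cross")
    merged = merged[merged["defined"]]
    r_het = association.pearson(merged["n_het_peus"], merged["mph"]).r
    r_gd = association.pearson(merged["gd"], merged["mph"]).r
    return {"r_het_peus": r_het, "r_gd": r_gd, "n_crosses": len(merged)}


def recovery_win_fraction(
    cfg: SimulationConfig, n_seeds: int = 50, base_seed: int = 0
) -> tuple[float, list[dict[str, float]]]:
    """Fraction of replicate seeds where the PEUS het count beats GD.

    A 'win' is r(n_het_peus, MPH) > r(GD, MPH) in one replicate. Seeds are
    base_seed .. base_seed + n_seeds - 1.
    """
    reps = [replicate_predictor_comparison(cfg, base_seed + s) for s in range(n_seeds)]
    wins = sum(r["r_het_peus"] > r["r_gd"] for r in reps)
    return wins / n_seeds, reps
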
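"""End-to-end orchestration: simulate/load -> per-locus metrics -> feature
matrix -> immune map -> heterogeneity report.

`run_pipeline` is a deterministic function of its inputs and the seed; the
manifest it returns records every parameter needed to reproduce the outputs
bitwise.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__, heterogeneity, neoantigens, panels, repertoire, scoring, variants
from .immune_map import ImmuneMapResult, build_immune_map
from .scoring import FeatureMatrix, SsgseaParams
from .simulate import CohortConfig, SyntheticCohort, generate_cohort
from .types import ExpressionMatrix, RepertoireTable, ValidationError, sample_id


@dataclass
class PipelineConfig:
    """Thresholds and stage parameters (defaults are the published values)."""

    neoantigen_mode: str = "strict"
    dominant_threshold: float = 0.005
    map_iterations: int = 100
    discovery_frac: float = 2.0 / 3.0
    ssgsea_alpha: float = 0.25
    het_method: str = "ith"  # ith | cv
    seed: int = 0


@dataclass
class PipelineResult:
    metrics: pd.DataFrame  # per-locus table
    features: FeatureMatrix
    immune_map: ImmuneMapResult
    patient_stats: pd.DataFrame  # per-patient ITH / CV / divergence
    correlations: dict
    manifest: dict = field(default_factory=dict)


def _check_sample_consistency(expr: ExpressionMatrix, rep: RepertoireTable) -> None:
    missing = sorted(set(expr.samples) - set(rep.samples))
    if missing:
        raise ValidationError(
            f"samples in expression but absent from repertoire: {missing[:5]}"
        )


def per_locus_metrics(cohort: SyntheticCohort, config: PipelineConfig) -> pd.DataFrame:
    """Per-(patient, locus) TMB, neoantigen load, repertoire and cytolytic
    metrics on the filtered mutation table."""
    filtered = variants.filter_mutations(cohort.mutations)
    tmb = variants.tmb_table(filtered)
    tmb.index = [sample_id(p, l) for p, l in tmb.index]

    # restrict affinity pairs to mutations that survive the somatic filter
    kept = {(r.patient_id, r.locus_id, r.gene, r.protein_change) for r in filtered}
    aff = cohort.affinities
    mask = [
        (p, l, g, c) in kept
        for p, l, g, c in zip(
            aff["patient_id"], aff["locus_id"], aff["gene"], aff["protein_change"]
        )
    ]
    strict = neoantigens.filter_neoantigens(aff[mask], config.neoantigen_mode)
    loads = neoantigens.neoantigen_load_table(strict)
    if not loads.empty:
        loads.index = [sample_id(p, l) for p, l in loads.index]

    rep_summary = repertoire.summarize_table(cohort.repertoire, config.dominant_threshold)
    cyto = scoring.cytolytic_activity(cohort.expression)

    sids = cohort.expression.samples
    out = pd.DataFrame(index=pd.Index(sids, name="sample_id"))
    out["tmb"] = tmb.reindex(sids).fillna(0).astype(int)
    out["neoantigen_load"] = loads.reindex(sids).fillna(0).astype(int)
    for col in ("richness", "shannon_entropy", "simpson_index", "clonality"):
        out[col] = rep_summary[col].reindex(sids)
    out["cytolytic_activity"] = cyto.reindex(sids)
    return out


def patient_heterogeneity_stats(
    cohort: SyntheticCohort, metrics: pd.DataFrame, cell_scores: pd.DataFrame
) -> pd.DataFrame:
    """Per-patient ITH, CV of burden, and infiltration divergence.

    ``cell_scores`` is the unity-normalized 28-type x samples matrix — the
    same values the immune-cell heat map plots.
    """
    filtered = variants.filter_mutations(cohort.mutations)
    patients = sorted({r.patient_id for r in filtered})
    rows = []
    for pat in patients:
        pres = variants.presence_matrix(filtered, pat)
        cols = [s for s in metrics.index if s.rsplit("_", 1)[0] == pat]
        row: dict = {"patient_id": pat, "n_loci": pres.shape[1]}
        row["ith"] = variants.ith(pres)
        tmbs = metrics.loc[cols, "tmb"]
        row["cv"] = variants.cv_tmb(tmbs) if len(cols) >= 2 and tmbs.mean() > 0 else np.nan
        if len(cols) >= 2:
            row["divergence"] = heterogeneity.infiltration_divergence(cell_scores[cols])
        else:
            row["divergence"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("patient_id")


def run_pipeline(
    cohort: SyntheticCohort | None = None,
    config: PipelineConfig = PipelineConfig(),
    cohort_config: CohortConfig | None = None,
) -> PipelineResult:
    """Run every stage on a provided or freshly simulated cohort."""
    if cohort is None:
        cohort_config = cohort_config or CohortConfig(seed=config.seed)
        cohort = generate_cohort(cohort_config)
    _check_sample_consistency(cohort.expression, cohort.repertoire)
    params = SsgseaParams(alpha=config.ssgsea_alpha)

    metrics = per_locus_metrics(cohort, config)
    features = scoring.assemble_features(
        cohort.expression,
        metrics["neoantigen_load"].astype(float),
        metrics["clonality"],
        panels.default_immune_gene_panel(),
        panels.default_pathway_sets(),
        panels.default_cell_type_sets(),
        params,
    )
    imap = build_immune_map(
        features,
        metrics["cytolytic_activity"],
        n_iter=config.map_iterations,
        seed=config.seed,
        discovery_frac=config.discovery_frac,
    )
    metrics = metrics.assign(immune_status=imap.labels)

    cell_scores = scoring.normalize_scores(
        scoring.ssgsea_matrix(cohort.expression, panels.default_cell_type_sets(), params),
        "unity",
    )
    pstats = patient_heterogeneity_stats(cohort, metrics, cell_scores)
    usable = pstats.dropna(subset=["divergence"])
    correlations = {
        "tmb_vs_clonality": heterogeneity.pearson(metrics["tmb"], metrics["clonality"]),
        "tmb_vs_cytolytic": heterogeneity.pearson(
            np.log2(metrics["tmb"] + 1.0), np.log2(metrics["cytolytic_activity"] + 1.0)
        ),
        "anti_vs_pro_tumor": heterogeneity.antitumor_protumor_correlation(cell_scores),
        "ith_vs_divergence": heterogeneity.het_vs_het(usable["ith"], usable["divergence"]),
        "cv_vs_divergence": heterogeneity.het_vs_het(
            usable["cv"].dropna(), usable["divergence"]
        ),
    }
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "pipeline": vars(config).copy(),
        "cohort": vars(cohort_config).copy() if cohort_config else None,
        "n_samples": len(metrics),
        "n_mutations": len(cohort.mutations),
    }
    return PipelineResult(metrics, features, imap, pstats, correlations, manifest)


def write_result(result: PipelineResult, outdir: str | os.PathLike) -> dict[str, str]:
    """Write all pipeline outputs as TSV/YAML under ``outdir``."""
    import yaml

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "metrics": os.path.join(outdir, "per_locus_metrics.tsv"),
        "features": os.path.join(outdir, "feature_matrix.tsv"),
        "proximity": os.path.join(outdir, "proximity.tsv"),
        "coords": os.path.join(outdir, "coords.tsv"),
        "labels": os.path.join(outdir, "labels.tsv"),
        "patient_stats": os.path.join(outdir, "patient_stats.tsv"),
        "correlations": os.path.join(outdir, "correlations.tsv"),
        "mixture": os.path.join(outdir, "mixture.yaml"),
        "manifest": os.path.join(outdir, "manifest.yaml"),
    }
    result.metrics.to_csv(paths["metrics"], sep="\t")
    result.features.df.rename_axis("sample_id").to_csv(paths["features"], sep="\t")
    result.immune_map.proximity.rename_axis("sample_id").to_csv(paths["proximity"], sep="\t")
    result.immune_map.coords.rename_axis("sample_id").to_csv(paths["coords"], sep="\t")
    result.immune_map.labels.rename_axis("sample_id").to_frame().to_csv(paths["labels"], sep="\t")
    result.patient_stats.to_csv(paths["patient_stats"], sep="\t")
    corr_rows = [
        {"comparison": k, "r": v.r, "p_value": v.p_value, "n": v.n,
         "ci_low": v.ci_low, "ci_high": v.ci_high}
        for k, v in result.correlations.items()
    ]
    pd.DataFrame(corr_rows).to_csv(paths["correlations"], sep="\t", index=False)
    gmm = result.immune_map.gmm
    mixture = {
        "weights": gmm.weights.tolist(),
        "means": gmm.means.tolist(),
        "covariances": gmm.covariances.tolist(),
        "hot_component": int(result.immune_map.hot_component),
        "component_cytolytic": result.immune_map.component_cytolytic.tolist(),
        "converged": bool(gmm.converged),
    }
    with open(paths["mixture"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(mixture, fh)
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(result.manifest, fh, sort_keys=False)
    return paths
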
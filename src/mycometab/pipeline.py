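"""End-to-end orchestration of the comparative metabolome analysis.

``run_full_analysis`` executes the whole Results sequence on one dataset
(synthetic by default, or files on disk): preprocessing, per-contrast
OPLS-DA with cross-validation and permutation significance, SUS loading
comparisons, set enrichment per contrast, per-treatment correlation networks,
and trajectory distances.  Everything is seeded and the written report bundle
is byte-identical across reruns of the same config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrichment as enr
from . import network as net
from . import trajectory as traj
from .compare import rf_mda_importance, sus_compare
from .containers import MetaboliteTable, read_table_tsv, write_table_tsv
from .io import read_annotation_tsv, read_gmt, write_annotation_tsv, write_gmt
from .preprocess import (
    autoscale,
    dixon_filter,
    knn_impute,
    log2_transform,
    normalize_internal_standard,
    normalize_sample_median,
)
from .projection import fit_opls, fit_oplsda, permutation_significance
from .simulate import (
    IS_FEATURE,
    SyntheticConfig,
    attach_pathways,
    make_pathway_sets,
    simulate_dataset,
)
from .stages import StageDesign, make_stage_design


@dataclass
class RunConfig:
    """Everything one analysis run needs; ``from_yaml`` reads the same fields."""

    seed: int = 0
    out_dir: str | Path = "results"
    # input: either a synthetic config or paths to matrix/annotation/GMT files
    synthetic: SyntheticConfig | None = None
    matrix_path: str | None = None
    annotation_path: str | None = None
    gmt_path: str | None = None
    # preprocessing
    dixon_alpha: float = 0.05
    knn_k: int | None = None
    # modelling
    contrasts: list[dict] | None = None       # None -> design defaults
    sus_pairs: list[tuple[str, str]] | None = None
    n_perm: int = 199
    cv_folds: int = 7
    rf_trees: int = 500
    # enrichment
    pathway_n_sets: int = 12
    pathway_size_range: tuple[int, int] = (5, 20)
    pathway_contamination: float = 0.1
    set_size_bounds: tuple[int, int] = (3, 60)
    msea_n_perm: int = 1999
    msea_weight: float = 1.0
    # network / trajectory
    network_alpha: float = 0.01
    strong_threshold: float = 0.7

    def __post_init__(self):
        if self.synthetic is None and self.matrix_path is None:
            self.synthetic = SyntheticConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        syn = doc.pop("synthetic", None)
        cfg = cls(**doc)
        if syn is not None:
            cfg.synthetic = SyntheticConfig(**syn)
        return cfg


def default_contrasts(design: StageDesign, das_points) -> list[dict]:
    """The study's contrast sequence for the sampled days.

    Mycorrhization contrasts at every stage reached by both treatments
    (matched by phenophase, not by calendar day), and consecutive-stage
    development contrasts within each treatment.
    """
    das_points = sorted(das_points)
    stage_at = {t: {d: design.stage(t, d) for d in das_points} for t in ("minusAM", "plusAM")}
    contrasts = []
    minus_stages = {s: d for d, s in stage_at["minusAM"].items()}
    plus_stages = {s: d for d, s in stage_at["plusAM"].items()}
    for stage in design.stages:
        if stage in minus_stages and stage in plus_stages:
            contrasts.append(
                {
                    "name": f"am_{stage}",
                    "kind": "am_effect",
                    "a": {"treatment": "minusAM", "das": [minus_stages[stage]]},
                    "b": {"treatment": "plusAM", "das": [plus_stages[stage]]},
                }
            )
    for treatment in ("minusAM", "plusAM"):
        for d1, d2 in zip(das_points, das_points[1:]):
            s1, s2 = stage_at[treatment][d1], stage_at[treatment][d2]
            contrasts.append(
                {
                    "name": f"dev_{treatment}_{s1}_{s2}",
                    "kind": "development",
                    "a": {"treatment": treatment, "das": [d1]},
                    "b": {"treatment": treatment, "das": [d2]},
                }
            )
    return contrasts


def default_sus_pairs(contrast_names: list[str]) -> list[tuple[str, str]]:
    """Loading comparisons mirroring the study: AM effects across stages,
    AM effect vs the development step it lags behind, and the two
    whole-course age models."""
    pairs = [("age_minusAM", "age_plusAM")]
    am = [n for n in contrast_names if n.startswith("am_")]
    for a, b in zip(am, am[1:]):
        pairs.append((a, b))
    dev_minus = [n for n in contrast_names if n.startswith("dev_minusAM")]
    for a, b in zip(dev_minus, dev_minus[1:]):
        pairs.append((a, b))
    if "am_SI" in contrast_names:
        lagged = [n for n in dev_minus if n.endswith("_SI")]
        if lagged:
            pairs.append(("am_SI", lagged[0]))
    return pairs


def _select(metadata: pd.DataFrame, group: dict, contrast_name: str) -> list[str]:
    ids = metadata.index[
        (metadata["treatment"] == group["treatment"])
        & (metadata["das"].isin(group["das"]))
    ]
    if len(ids) == 0:
        raise ValueError(
            f"contrast {contrast_name!r}: no samples for treatment "
            f"{group['treatment']!r} at das {group['das']}"
        )
    return list(ids)


def fit_contrast(
    imputed: MetaboliteTable,
    metadata: pd.DataFrame,
    contrast: dict,
    n_perm: int = 199,
    cv_folds: int = 7,
    seed: int = 0,
):
    """Subset-autoscale the two groups, fit OPLS-DA, validate by permutation.

    Returns (model, summary dict).  The positive class is group ``b`` (the
    inoculated treatment or the later stage), so positive loadings mean
    "higher under mycorrhization" / "accumulates with development".
    """
    ids_a = _select(metadata, contrast["a"], contrast["name"])
    ids_b = _select(metadata, contrast["b"], contrast["name"])
    ids = ids_a + ids_b
    sub = MetaboliteTable(imputed.values.loc[ids], imputed.state)
    scaled, _ = autoscale(sub)
    labels = ["a"] * len(ids_a) + ["b"] * len(ids_b)
    model = fit_oplsda(
        scaled.values, labels, positive_class="b", auto_select=True,
        cv_folds=cv_folds, seed=seed,
    )
    y = np.array([1.0 if l == "b" else 0.0 for l in labels])
    p_r2y, p_q2y = permutation_significance(
        scaled.values, y, {"kind": "OPLSDA", "n_orth": model.n_orth},
        n_perm=n_perm, seed=seed, n_folds=cv_folds, labels=labels,
    )
    model.perm_p_r2y, model.perm_p_q2y = p_r2y, p_q2y
    summary = {
        "name": contrast["name"],
        "kind": contrast.get("kind", "contrast"),
        "n_samples": len(ids),
        "n_orth": model.n_orth,
        "r2x_pred": round(model.r2x[0], 4),
        "r2x_total": round(float(sum(model.r2x)), 4),
        "r2y": round(model.r2y, 4),
        "q2y": None if model.q2y is None else round(model.q2y, 4),
        "perm_p_r2y": p_r2y,
        "perm_p_q2y": p_q2y,
    }
    return model, summary


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the full pipeline and write the report bundle to ``out_dir``."""
    design = make_stage_design()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- inputs -----------------------------------------------------------
    if config.matrix_path is not None:
        raw, metadata = read_table_tsv(config.matrix_path)
        annotation = read_annotation_tsv(config.annotation_path)
        sets, _ = read_gmt(config.gmt_path)
    else:
        syn = config.synthetic
        raw, metadata, annotation, truth = simulate_dataset(syn, design)
        sets, descriptions = make_pathway_sets(
            annotation,
            n_sets=config.pathway_n_sets,
            size_range=config.pathway_size_range,
            contamination=config.pathway_contamination,
            seed=syn.seed,
        )
        annotation = attach_pathways(annotation, sets)
        write_table_tsv(raw, metadata, out / "matrix_raw.tsv")
        write_annotation_tsv(annotation, out / "annotation.tsv")
        write_gmt(sets, out / "pathways.gmt", descriptions)
        truth.to_json(out / "ground_truth.json")

    # ---- preprocessing ----------------------------------------------------
    t = normalize_internal_standard(raw, IS_FEATURE)
    t = normalize_sample_median(t)
    t, dixon_mask = dixon_filter(t, metadata, alpha=config.dixon_alpha)
    t = log2_transform(t)
    imputed, impute_record = knn_impute(t, metadata, k=config.knn_k)
    scaled, scale_record = autoscale(imputed)
    provenance = {
        "seed": config.seed,
        "dixon_alpha": config.dixon_alpha,
        "n_dixon_excluded": int(dixon_mask.to_numpy().sum()),
        "n_imputed": len(impute_record["imputed_cells"]),
        "n_structural": len(impute_record["structural_cells"]),
        "dropped_features": scale_record["dropped_features"],
    }

    # ---- contrasts --------------------------------------------------------
    contrasts = config.contrasts or default_contrasts(design, sorted(metadata["das"].unique()))
    models: dict = {}
    summaries = []
    for i, contrast in enumerate(contrasts):
        model, summary = fit_contrast(
            imputed, metadata, contrast,
            n_perm=config.n_perm, cv_folds=config.cv_folds,
            seed=int(np.random.default_rng([config.seed, i]).integers(2**31)),
        )
        models[contrast["name"]] = model
        summaries.append(summary)

    # whole-course OPLS with calendar age as response, per treatment
    age_models: dict = {}
    mda_tables = {}
    for ti, treatment in enumerate(("minusAM", "plusAM")):
        ids = list(metadata.index[metadata["treatment"] == treatment])
        X = scaled.values.loc[ids]
        das = metadata.loc[ids, "das"].to_numpy(dtype=float)
        m = fit_opls(X, das, n_orth=1)
        age_models[f"age_{treatment}"] = m
        mda = rf_mda_importance(
            X, metadata.loc[ids, "das"].astype(str), n_trees=config.rf_trees,
            seed=int(np.random.default_rng([config.seed, 97, ti]).integers(2**31)),
        )
        mda_tables[treatment] = mda
    models.update(age_models)

    # ---- SUS comparisons --------------------------------------------------
    sus_pairs = config.sus_pairs or default_sus_pairs([c["name"] for c in contrasts])
    sus_results = {}
    for a, b in sus_pairs:
        if a not in models or b not in models:
            raise ValueError(f"SUS pair ({a}, {b}) references an unknown model")
        res = sus_compare(models[a], models[b])
        sus_results[f"{a}__vs__{b}"] = res

    # ---- enrichment -------------------------------------------------------
    curated, curation_log = enr.curate_sets(
        sets, annotation, min_size=config.set_size_bounds[0], max_size=config.set_size_bounds[1]
    )
    enrichment_tables = {}
    for i, contrast in enumerate(contrasts):
        model = models[contrast["name"]]
        ranking = model.predictive_loadings()
        enrichment_tables[contrast["name"]] = enr.msea(
            ranking, curated, n_perm=config.msea_n_perm,
            weight_exponent=config.msea_weight,
            seed=int(np.random.default_rng([config.seed, 211, i]).integers(2**31)),
        )

    # ---- networks ---------------------------------------------------------
    network_reports = {}
    corrs = {}
    pathway_groups = {
        name: members for name, members in curated.items()
    }
    for treatment in ("minusAM", "plusAM"):
        means = net.stage_means(scaled, metadata, treatment)
        corr = net.pairwise_pearson(means)
        corrs[treatment] = corr
        g = net.build_network(corr, alpha=config.network_alpha)
        stats = net.graph_stats(g)
        strong = net.strong_link_counts(corr, threshold=config.strong_threshold)
        groups = net.group_correlation_summary(corr, pathway_groups)
        network_reports[treatment] = {
            "stats": stats,
            "n_strong_links_total": int(strong["n_strong"].sum() // 2),
            "group_summary": groups.round(6).to_dict(orient="records"),
        }
        net.write_edge_list(g, out / f"network_{treatment}_edges.tsv")
    rho_cc, p_cc = net.correlation_of_correlations(corrs["minusAM"], corrs["plusAM"])

    # ---- trajectory -------------------------------------------------------
    centroids = traj.stage_centroids(scaled, metadata, design)
    stage_order = {
        t: [design.stage(t, d) for d in sorted(metadata["das"].unique())]
        for t in ("minusAM", "plusAM")
    }
    trajectory = traj.path_distances(centroids, stage_order)
    gaps = traj.treatment_gaps(centroids, design, sorted(metadata["das"].unique()))

    # ---- bundle -----------------------------------------------------------
    report = {
        "seed": config.seed,
        "provenance": provenance,
        "models": summaries,
        "age_models": {
            name: {"r2x_pred": round(m.r2x[0], 4), "r2y": round(m.r2y, 4)}
            for name, m in sorted(age_models.items())
        },
        "sus": {
            key: {"rho": round(r.spearman_rho, 4), "p": float(r.p_value)}
            for key, r in sorted(sus_results.items())
        },
        "curation": curation_log,
        "network": network_reports,
        "correlation_of_correlations": {"rho": round(rho_cc, 4), "p": p_cc},
        "trajectory": trajectory.to_dict(),
        "treatment_gaps": gaps.round(6).to_dict(orient="records"),
    }
    _write_json(report, out / "report.json")
    for key, res in sus_results.items():
        res.table.round(6).to_csv(out / f"sus_{key}.tsv", sep="\t", index=False)
    for name, tab in enrichment_tables.items():
        tab.round(6).to_csv(out / f"enrichment_{name}.tsv", sep="\t", index=False)
    for treatment, mda in mda_tables.items():
        mda.round(6).to_csv(out / f"mda_{treatment}.tsv", sep="\t", header=True)
    with open(out / "models.json", "w") as fh:
        json.dump({k: m.to_dict() for k, m in sorted(models.items())}, fh, sort_keys=True)
    return report


def _write_json(doc, path) -> None:
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
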
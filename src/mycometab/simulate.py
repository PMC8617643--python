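"""Seeded generator of synthetic leaf-metabolome datasets with ground truth.

The generator reproduces the study design the rest of the package analyses:
two treatments (``minusAM``/``plusAM``), leaf sampling at 14/24/29/45/52 DAS
with three biological replicates, and ~320 GC-MS features with the reported
chemical-class composition (86 sugars, 25 amino acids, 12 carboxylic acids,
8 fatty acids, 5 phosphates, the rest mixed/unknown).

Planted structure, all recorded in :class:`GroundTruth`:

* per-class developmental trajectories over the phenophase order (sugars
  accumulate, amino and carboxylic acids decline);
* the +AM stage advance of the phenology design (a +AM plant at a given DAS
  sits one phenophase later than the control);
* a +AM *sugar lag*: sugar features of +AM samples follow the trajectory of
  the stage ``sugar_lag_stages`` positions earlier, so mycorrhized plants
  reach each phenophase before completing its sugar accumulation;
* +AM phosphate elevation (Pi x2.0, glycerophosphoglycerol x5.6);
* multiplicative per-sample loading factors removed exactly by the spiked
  internal-standard feature;
* technical dropouts (low values), gross spike outliers, and whole-group
  structural absences, each with its own boolean mask.

On the log2 scale the planted signal is::

    x_ij = mu_j + f_class(j)(stage_eff(treatment_i, das_i)) + beta_j * [+AM] + eps_ij

with ``eps ~ N(0, sigma_bio^2)``; the reported raw peak area is
``2**x_ij * L_i`` next to an internal-standard column with area ``L_i``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MetaboliteTable
from .stages import StageDesign, make_stage_design

IS_FEATURE = "IS_tricosane"

#: chemical classes in the order identification labels are assigned
CLASS_ORDER = (
    "amino_acids",
    "carboxylic_acids",
    "fatty_acids",
    "phosphates",
    "sugars",
    "other",
)

DEFAULT_CLASS_COUNTS = {
    "sugars": 86,
    "amino_acids": 25,
    "carboxylic_acids": 12,
    "fatty_acids": 8,
    "phosphates": 5,
    "other": 184,
}

_CLASS_PREFIX = {
    "sugars": "sugar",
    "amino_acids": "amino",
    "carboxylic_acids": "carbox",
    "fatty_acids": "fatty",
    "phosphates": "phos",
    "other": "other",
}


@dataclass
class SyntheticConfig:
    """Study-design parameters of the generator (defaults = study conditions)."""

    n_replicates: int = 3
    das_points: tuple[int, ...] = (14, 24, 29, 45, 52)
    class_counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    sigma_bio: float = 0.2          # replicate noise SD, log2 units
    dropout_rate: float = 0.02      # probability a low value goes missing
    outlier_rate: float = 0.005     # probability of a gross spike
    structural_rate: float = 0.01   # probability a (feature, group) is absent entirely
    am_phosphate_fold: dict[str, float] = field(
        default_factory=lambda: {"Pi": 2.0, "glycerophosphoglycerol": 5.6}
    )
    sugar_lag_stages: int = 1
    traj_amplitude: float = 3.5     # full log2 range of the sugar/acid trajectories
    loading_sigma: float = 0.2      # SD of log loading factor L_i
    baseline_mean: float = 8.0      # mean of per-feature baseline mu_j (log2)
    baseline_sd: float = 1.5
    n_identified: int = 83
    n_class_only: int = 80
    das_only_signal: bool = False   # diagnostic switch: trajectories follow DAS, not stage
    seed: int = 0

    def validate(self, design: StageDesign) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for c, n in self.class_counts.items():
            if n <= 0:
                raise ValueError(f"class count for {c!r} must be > 0")
        for r in (self.dropout_rate, self.outlier_rate, self.structural_rate):
            if not 0.0 <= r <= 0.5:
                raise ValueError("rates must be in [0, 0.5]")
        for f in self.am_phosphate_fold.values():
            if f <= 0:
                raise ValueError("phosphate folds must be > 0")
        domain = set(design.das_points)
        bad = [d for d in self.das_points if d not in domain]
        if bad:
            raise ValueError(f"das points {bad} outside the stage-design domain {sorted(domain)}")


@dataclass
class GroundTruth:
    """Everything planted by the generator, for recovery testing."""

    class_trajectory: dict          # (class, stage) -> mean log2 shift
    traj_pattern: dict              # (class, stage) -> unit pattern scaled per feature
    feature_traj_weight: pd.Series  # a_j: per-feature trajectory amplitude
    feature_baseline: pd.Series     # mu_j
    am_effect: pd.Series            # beta_j, log2 fold of the +AM shift
    lag_applied: pd.Series          # bool, sugar-lag features
    loading_factor: pd.Series       # L_i > 0 per sample
    planted_log2: pd.DataFrame      # noise-free x_ij (samples x features)
    dropout_mask: pd.DataFrame      # technical dropouts
    outlier_mask: pd.DataFrame      # gross spikes
    structural_mask: pd.DataFrame   # whole-group absences

    def to_json(self, path) -> None:
        doc = {
            "class_trajectory": {f"{c}|{s}": v for (c, s), v in self.class_trajectory.items()},
            "traj_pattern": {f"{c}|{s}": v for (c, s), v in self.traj_pattern.items()},
            "feature_traj_weight": self.feature_traj_weight.round(10).to_dict(),
            "feature_baseline": self.feature_baseline.round(10).to_dict(),
            "am_effect": self.am_effect.round(10).to_dict(),
            "lag_applied": {k: bool(v) for k, v in self.lag_applied.items()},
            "loading_factor": self.loading_factor.round(10).to_dict(),
            "dropout_cells": _mask_cells(self.dropout_mask),
            "outlier_cells": _mask_cells(self.outlier_mask),
            "structural_cells": _mask_cells(self.structural_mask),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)


def _mask_cells(mask: pd.DataFrame) -> list[list[str]]:
    rows, cols = np.nonzero(mask.to_numpy())
    return [[str(mask.index[i]), str(mask.columns[j])] for i, j in zip(rows, cols)]


# ---------------------------------------------------------------------------
# feature universe

def _feature_frame(class_counts: dict[str, int]) -> pd.DataFrame:
    rows = []
    for cls in CLASS_ORDER:
        n = class_counts.get(cls, 0)
        prefix = _CLASS_PREFIX.get(cls, cls)
        for i in range(n):
            if cls == "phosphates" and i == 0:
                fid = "Pi"
            elif cls == "phosphates" and i == 1:
                fid = "glycerophosphoglycerol"
            else:
                fid = f"{prefix}_{i + 1:03d}"
            rows.append((fid, cls))
    return pd.DataFrame(rows, columns=["feature_id", "chemical_class"])


def _assign_identification(features: pd.DataFrame, n_identified: int, n_class_only: int) -> pd.Series:
    """Identification level per feature: small named classes first, then sugars.

    Mirrors the reported composition: the exactly identified compounds are the
    named amino/carboxylic/fatty acids and phosphates plus part of the sugars;
    class-only features are the remaining sugars and part of the mixed pool.
    """
    total = len(features)
    if n_identified + n_class_only > total:
        raise ValueError("identification counts exceed the feature universe")
    label = pd.Series("unknown", index=features.index)
    order = []
    for cls in CLASS_ORDER:
        order.extend(features.index[features["chemical_class"] == cls])
    ident = order[:n_identified]
    class_only = order[n_identified : n_identified + n_class_only]
    label.loc[ident] = "identified"
    label.loc[class_only] = "class_only"
    return label


def _class_trajectories(design: StageDesign, amplitude: float) -> tuple[dict, dict]:
    """Monotone per-class stage patterns and the implied class-mean shifts.

    Every feature follows its class pattern scaled by an individual amplitude
    weight ``a_j`` (drawn in :func:`simulate_dataset`): named classes get
    ``a_j ~ U(0.5, 1.5)`` (mean 1, so the class-mean shift equals the
    pattern), the mixed ``other`` pool gets ``a_j ~ U(-1, 1)`` (individually
    varied monotone trends with zero class mean), matching the observed mix
    of compounds rising and falling with development.
    """
    k = len(design.stages)
    up = np.linspace(-amplitude / 2, amplitude / 2, k)
    down = -up
    # phosphates carry no developmental trend: their planted signal is the
    # treatment fold alone, so the fold is identifiable at any stage pairing
    per_class = {
        "sugars": up,
        "amino_acids": down,
        "carboxylic_acids": down,
        "fatty_acids": up / 2,
        "phosphates": np.zeros(k),
        "other": up,
    }
    mean_weight = {c: 1.0 for c in per_class}
    mean_weight["other"] = 0.0
    pattern = {
        (cls, stage): float(vals[i])
        for cls, vals in per_class.items()
        for i, stage in enumerate(design.stages)
    }
    mean_shift = {
        (cls, stage): pattern[(cls, stage)] * mean_weight[cls]
        for cls, stage in pattern
    }
    return pattern, mean_shift


# ---------------------------------------------------------------------------
# main generator

def simulate_dataset(
    config: SyntheticConfig, design: StageDesign | None = None
) -> tuple[MetaboliteTable, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (raw table, metadata, annotation, ground truth) from a config.

    Identical configs (including seed) produce identical output, byte for
    byte once written with the package writers.
    """
    design = design or make_stage_design()
    config.validate(design)
    rng = np.random.default_rng(config.seed)

    features = _feature_frame(config.class_counts)
    features["identification"] = _assign_identification(
        features, config.n_identified, config.n_class_only
    )
    feature_ids = list(features["feature_id"])
    classes = pd.Series(features["chemical_class"].values, index=feature_ids)

    # sample layout
    meta_rows = []
    for treatment in ("minusAM", "plusAM"):
        for das in config.das_points:
            for rep in range(1, config.n_replicates + 1):
                sid = f"{treatment}_d{das:02d}_r{rep}"
                meta_rows.append((sid, treatment, das, rep))
    metadata = pd.DataFrame(
        meta_rows, columns=["sample_id", "treatment", "das", "replicate"]
    ).set_index("sample_id")

    # planted per-feature parameters
    baseline = pd.Series(
        rng.normal(config.baseline_mean, config.baseline_sd, len(feature_ids)),
        index=feature_ids,
        name="baseline",
    )
    am_effect = pd.Series(0.0, index=feature_ids, name="am_effect")
    for name, fold in config.am_phosphate_fold.items():
        if name not in am_effect.index:
            raise ValueError(f"am_phosphate_fold names unknown feature {name!r}")
        am_effect[name] = np.log2(fold)
    lag_applied = pd.Series(classes.eq("sugars").values, index=feature_ids, name="lag_applied")

    pattern, mean_shift = _class_trajectories(design, config.traj_amplitude)
    weights = np.where(
        classes.eq("other").to_numpy(),
        rng.uniform(-1.0, 1.0, len(feature_ids)),
        rng.uniform(0.5, 1.5, len(feature_ids)),
    )
    traj_weight = pd.Series(weights, index=feature_ids, name="traj_weight")

    # noise-free log2 signal
    planted = np.empty((len(metadata), len(feature_ids)))
    for i, sid in enumerate(metadata.index):
        treatment = metadata.at[sid, "treatment"]
        das = int(metadata.at[sid, "das"])
        signal_treatment = "minusAM" if config.das_only_signal else treatment
        stage = design.stage(signal_treatment, das)
        for j, fid in enumerate(feature_ids):
            eff_stage = stage
            if treatment == "plusAM" and lag_applied[fid] and not config.das_only_signal:
                eff_stage = design.shift(stage, -config.sugar_lag_stages)
            x = baseline[fid] + traj_weight[fid] * pattern[(classes[fid], eff_stage)]
            if treatment == "plusAM":
                x += am_effect[fid]
            planted[i, j] = x
    planted = pd.DataFrame(planted, index=metadata.index, columns=feature_ids)

    noisy = planted + rng.normal(0.0, config.sigma_bio, planted.shape)

    # raw areas with per-sample loading factors and an internal standard
    loading = pd.Series(
        np.exp(rng.normal(0.0, config.loading_sigma, len(metadata))),
        index=metadata.index,
        name="loading_factor",
    )
    areas = np.power(2.0, noisy).mul(loading, axis=0)

    # gross spike outliers (flaggable by a Dixon test at n = 3)
    outlier_mask = pd.DataFrame(
        rng.random(areas.shape) < config.outlier_rate,
        index=areas.index,
        columns=areas.columns,
    )
    spike = rng.uniform(5.0, 20.0, areas.shape)
    areas = areas.where(~outlier_mask, areas * spike)

    # technical dropouts: the low half of each feature's values is eligible
    # at twice the nominal rate, so overall missingness equals dropout_rate
    ranks = areas.rank(axis=0, method="first")
    low_half = ranks.le(len(areas) / 2)
    dropout_mask = pd.DataFrame(
        (rng.random(areas.shape) < 2.0 * config.dropout_rate) & low_half.to_numpy(),
        index=areas.index,
        columns=areas.columns,
    )

    # structural absences: a (feature, replicate-group) missing entirely
    structural_mask = pd.DataFrame(False, index=areas.index, columns=areas.columns)
    for (_, _), sample_ids in metadata.groupby(["treatment", "das"], sort=True).groups.items():
        absent = rng.random(len(feature_ids)) < config.structural_rate
        structural_mask.loc[list(sample_ids), np.array(feature_ids)[absent]] = True

    areas = areas.mask(dropout_mask | structural_mask)
    areas[IS_FEATURE] = loading  # internal standard: constant true amount 1.0

    truth = GroundTruth(
        class_trajectory=mean_shift,
        traj_pattern=pattern,
        feature_traj_weight=traj_weight,
        feature_baseline=baseline,
        am_effect=am_effect,
        lag_applied=lag_applied,
        loading_factor=loading,
        planted_log2=planted,
        dropout_mask=dropout_mask,
        outlier_mask=outlier_mask,
        structural_mask=structural_mask,
    )
    annotation = features.copy()
    annotation["pathway_ids"] = [[] for _ in range(len(annotation))]
    return MetaboliteTable(areas, "raw"), metadata, annotation, truth


# ---------------------------------------------------------------------------
# pathway sets

def make_pathway_sets(
    annotation: pd.DataFrame,
    n_sets: int = 12,
    size_range: tuple[int, int] = (5, 20),
    contamination: float = 0.0,
    seed: int = 0,
) -> tuple[dict[str, list[str]], dict[str, str]]:
    """Class-coherent named feature sets emulating curated pathway lists.

    Sets are drawn from the *identified* features of a chemical class, with a
    configurable fraction of cross-class contamination.  Returns ``(sets,
    descriptions)``; write with :func:`mycometab.io.write_gmt`.
    """
    if annotation.empty:
        raise ValueError("annotation table is empty")
    lo, hi = size_range
    if lo < 1 or hi < lo:
        raise ValueError(f"bad size_range {size_range}")
    if not 0.0 <= contamination <= 1.0:
        raise ValueError("contamination must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ident = annotation[annotation["identification"] == "identified"]
    pools = {
        cls: list(sub["feature_id"])
        for cls, sub in ident.groupby("chemical_class", sort=True)
        if len(sub) >= lo
    }
    if not pools:
        raise ValueError(f"size_range {size_range} infeasible: no class has >= {lo} identified features")
    all_ident = list(ident["feature_id"])
    class_names = sorted(pools)
    weights = np.array([len(pools[c]) for c in class_names], dtype=float)
    weights /= weights.sum()

    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for i in range(n_sets):
        cls = class_names[int(rng.choice(len(class_names), p=weights))]
        pool = pools[cls]
        size = int(rng.integers(lo, min(hi, len(pool)) + 1))
        members = list(rng.choice(pool, size=size, replace=False))
        if contamination > 0:
            outside = [f for f in all_ident if f not in pool]
            for k in range(size):
                if outside and rng.random() < contamination:
                    members[k] = str(rng.choice(outside))
        members = sorted(set(members))
        name = f"path_{cls}_{i + 1:02d}"
        sets[name] = members
        descriptions[name] = f"synthetic {cls} pathway"
    return sets, descriptions


def attach_pathways(annotation: pd.DataFrame, sets: dict[str, list[str]]) -> pd.DataFrame:
    """Fill the annotation's pathway_ids column from a set collection."""
    membership: dict[str, list[str]] = {f: [] for f in annotation["feature_id"]}
    for name, members in sets.items():
        for f in members:
            if f in membership:
                membership[f].append(name)
    out = annotation.copy()
    out["pathway_ids"] = [sorted(membership[f]) for f in out["feature_id"]]
    return out
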
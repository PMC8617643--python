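"""Distances travelled in normalized metabolite space.

Each (treatment, stage) group is reduced to its centroid in the standardized
feature space; consecutive-stage Euclidean segment lengths, cumulative path
lengths, the non-additivity of nested segments (how much longer the walked
path is than the straight line), and the +AM/-AM gaps at matched stages and
matched days quantify the scale of developmental vs mycorrhizal change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stages import StageDesign


@dataclass
class TrajectoryResult:
    centroids: dict                      # (treatment, stage) -> vector
    segments: pd.DataFrame               # treatment, from, to, length, cumulative
    nonadditivity: pd.DataFrame          # treatment, from, to, nested_sum, direct, index

    def to_dict(self) -> dict:
        return {
            "segments": self.segments.round(6).to_dict(orient="records"),
            "nonadditivity": self.nonadditivity.round(6).to_dict(orient="records"),
        }


def stage_centroids(table, metadata: pd.DataFrame, design: StageDesign) -> dict:
    """Mean feature vector per (treatment, stage); stage from the design map."""
    values = table.values if hasattr(table, "state") else table
    centroids: dict = {}
    for (treatment, das), sub in metadata.groupby(["treatment", "das"], sort=True):
        ids = list(sub.index)
        if not ids:
            raise ValueError(f"empty group ({treatment}, {das})")
        stage = design.stage(treatment, int(das))
        centroids[(treatment, stage)] = values.loc[ids].mean(axis=0).to_numpy()
    return centroids


def path_distances(centroids: dict, stage_order: dict[str, list[str]]) -> TrajectoryResult:
    """Segment/cumulative lengths and nested non-additivity per treatment.

    ``stage_order`` maps treatment -> ordered list of stages to walk; every
    named stage must have a centroid.  Non-additivity of a super-segment
    (i, j) is (sum of nested segment lengths) / (direct distance) - 1; a
    zero direct distance with a non-zero path is reported as ``inf``.
    """
    seg_rows = []
    nad_rows = []
    for treatment, order in stage_order.items():
        if len(order) < 2:
            raise ValueError(f"need >= 2 ordered stages for {treatment!r}")
        missing = [s for s in order if (treatment, s) not in centroids]
        if missing:
            raise ValueError(f"missing centroids for {treatment!r}: {missing}")
        pts = [np.asarray(centroids[(treatment, s)], dtype=float) for s in order]
        lengths = [float(np.linalg.norm(b - a)) for a, b in zip(pts, pts[1:])]
        cum = np.cumsum(lengths)
        for k, (a, b) in enumerate(zip(order, order[1:])):
            seg_rows.append(
                {"treatment": treatment, "from": a, "to": b,
                 "length": lengths[k], "cumulative": float(cum[k])}
            )
        for i in range(len(order)):
            for j in range(i + 2, len(order)):
                nested = float(sum(lengths[i:j]))
                direct = float(np.linalg.norm(pts[j] - pts[i]))
                index = nested / direct - 1.0 if direct > 0 else float("inf")
                nad_rows.append(
                    {"treatment": treatment, "from": order[i], "to": order[j],
                     "nested_sum": nested, "direct": direct, "index": index}
                )
    return TrajectoryResult(
        centroids=centroids,
        segments=pd.DataFrame(seg_rows),
        nonadditivity=pd.DataFrame(nad_rows),
    )


def treatment_gaps(centroids: dict, design: StageDesign,
                   das_points=None) -> pd.DataFrame:
    """+AM vs -AM centroid distances matched by stage and, separately, by DAS."""
    treatments = sorted({t for t, _ in centroids})
    if set(treatments) != {"minusAM", "plusAM"}:
        raise ValueError("both treatments required")
    rows = []
    minus_stages = {s for t, s in centroids if t == "minusAM"}
    plus_stages = {s for t, s in centroids if t == "plusAM"}
    for stage in sorted(minus_stages & plus_stages, key=design.index):
        d = float(np.linalg.norm(
            np.asarray(centroids[("plusAM", stage)]) - np.asarray(centroids[("minusAM", stage)])
        ))
        rows.append({"match": "stage", "key": stage, "distance": d})
    das_points = das_points or design.das_points
    for das in das_points:
        try:
            sm = design.stage("minusAM", das)
            sp = design.stage("plusAM", das)
        except KeyError:
            continue
        if ("minusAM", sm) in centroids and ("plusAM", sp) in centroids:
            d = float(np.linalg.norm(
                np.asarray(centroids[("plusAM", sp)]) - np.asarray(centroids[("minusAM", sm)])
            ))
            rows.append({"match": "das", "key": str(das), "distance": d})
    return pd.DataFrame(rows)
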
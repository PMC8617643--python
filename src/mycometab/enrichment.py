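"""Preranked metabolite set enrichment (MSEA).

Features are ranked by a model statistic (here: predictive-component
loadings) and each curated metabolite set is scored with the weighted
Kolmogorov-Smirnov running sum of preranked GSEA: walking down the ranking,
the sum rises by ``|stat|^w / N_R`` at set members and falls by
``1/(N - n_set)`` elsewhere; the enrichment score (ES) is the extremum.
Significance comes from random same-size feature sets, normalisation (NES)
from the sign-matched null mean, and Benjamini-Hochberg adjustment is
applied across sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests


@dataclass
class EnrichmentResult:
    name: str
    size: int
    es: float
    nes: float
    p_value: float
    p_adjusted: float
    leading_edge: list[str]


def curate_sets(
    sets: dict[str, list[str]],
    annotation: pd.DataFrame,
    min_size: int = 3,
    max_size: int = 60,
) -> tuple[dict[str, list[str]], dict]:
    """Intersect sets with the universe, join class-only features, apply size bounds.

    Features identified only to chemical class (hexose, disaccharide, ...)
    are added to every set whose members are predominantly of that class.
    Sets falling outside [min_size, max_size] after curation are dropped and
    recorded in the returned log.
    """
    universe = set(annotation["feature_id"])
    cls = dict(zip(annotation["feature_id"], annotation["chemical_class"]))
    class_only = annotation[annotation["identification"] == "class_only"]
    by_class: dict[str, list[str]] = {}
    for f, c in zip(class_only["feature_id"], class_only["chemical_class"]):
        by_class.setdefault(c, []).append(f)

    curated: dict[str, list[str]] = {}
    log = {"dropped_small": [], "dropped_large": []}
    for name, members in sets.items():
        kept = [f for f in members if f in universe]
        if kept:
            counts = pd.Series([cls[f] for f in kept]).value_counts()
            dominant = counts.index[0]
            joined = set(kept) | set(by_class.get(dominant, []))
        else:
            joined = set()
        final = sorted(joined)
        if len(final) < min_size:
            log["dropped_small"].append(name)
        elif len(final) > max_size:
            log["dropped_large"].append(name)
        else:
            curated[name] = final
    if not curated:
        raise ValueError("no sets survive curation")
    return curated, log


def _sorted_ranking(ranking: pd.Series) -> tuple[list, np.ndarray]:
    """Feature ids and statistics sorted by decreasing statistic (id tiebreak)."""
    ids = sorted(ranking.index, key=lambda f: (-float(ranking[f]), str(f)))
    return ids, np.array([float(ranking[f]) for f in ids])


def _es_core(stat_sorted: np.ndarray, hit: np.ndarray, weight_exponent: float) -> tuple[float, int]:
    """ES and extremum position from pre-sorted statistics and a hit mask."""
    n = stat_sorted.size
    n_hit = int(hit.sum())
    if n_hit == 0 or n_hit == n:
        return 0.0, -1
    w = np.abs(stat_sorted) ** weight_exponent
    wh = np.where(hit, w, 0.0)
    denom = wh.sum()
    if denom == 0:  # all member statistics zero: fall back to unweighted hits
        wh = hit.astype(float)
        denom = float(n_hit)
    running = np.cumsum(wh) / denom - np.cumsum(~hit) / (n - n_hit)
    i_ext = int(np.argmax(np.abs(running)))
    return float(running[i_ext]), i_ext


def enrichment_score(
    ranking: pd.Series, members, weight_exponent: float = 1.0
) -> tuple[float, list[str]]:
    """ES and leading edge of one set against a complete ranking.

    ``ranking`` maps every feature to its statistic.  Raises if the set
    strays outside the universe; a set equal to the whole universe has no
    misses and scores 0.
    """
    members = set(members)
    if not members <= set(ranking.index):
        missing = sorted(members - set(ranking.index))
        raise ValueError(f"set members outside the ranked universe: {missing[:5]}")
    ids, stat_sorted = _sorted_ranking(ranking)
    hit = np.fromiter((f in members for f in ids), dtype=bool, count=len(ids))
    es, i_ext = _es_core(stat_sorted, hit, weight_exponent)
    if i_ext < 0:
        return es, []
    if es >= 0:
        leading = [f for k, f in enumerate(ids) if k <= i_ext and hit[k]]
    else:
        leading = [f for k, f in enumerate(ids) if k > i_ext and hit[k]]
    return es, leading


def msea(
    ranking: pd.Series,
    sets: dict[str, list[str]],
    n_perm: int = 1999,
    weight_exponent: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Set enrichment over random same-size feature sets.

    Per set: ES, NES = ES / mean(|null ES| of the same sign), sign-matched
    permutation p-value, and BH-adjusted p across sets.  Deterministic given
    ``seed``.
    """
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19")
    rng = np.random.default_rng(seed)
    ids, stat_sorted = _sorted_ranking(ranking)
    n = len(ids)
    rows = []
    null_cache: dict[int, np.ndarray] = {}
    for name in sets:
        members = sets[name]
        es, leading = enrichment_score(ranking, members, weight_exponent)
        size = len(set(members))
        if size not in null_cache:
            null = np.empty(n_perm)
            for b in range(n_perm):
                hit = np.zeros(n, dtype=bool)
                hit[rng.choice(n, size=size, replace=False)] = True
                null[b], _ = _es_core(stat_sorted, hit, weight_exponent)
            null_cache[size] = null
        null = null_cache[size]
        same_sign = null >= 0 if es >= 0 else null < 0
        n_sign = int(same_sign.sum())
        extreme = int(np.sum(same_sign & (np.abs(null) >= abs(es) - 1e-15)))
        p = (1 + extreme) / (n_sign + 1)
        mean_mag = float(np.mean(np.abs(null[same_sign]))) if n_sign else float("nan")
        nes = es / mean_mag if n_sign and mean_mag > 0 else float("nan")
        rows.append(
            {
                "set": name, "size": size, "es": es, "nes": nes,
                "p_value": p, "leading_edge": ";".join(leading),
            }
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out[["set", "size", "es", "nes", "p_value", "p_adjusted", "leading_edge"]]
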
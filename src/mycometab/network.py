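"""Correlation networks over stage-mean metabolite profiles.

Metabolites are mapped by Pearson correlation of their mean levels across
the sampled time points of one treatment; edges keep pairs whose correlation
is significant at ``alpha`` (two-sided t-approximation, df = n-2).  Topology
statistics (diameter, average shortest path) follow the largest-connected-
component convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CorrMatrix:
    r: pd.DataFrame
    p: pd.DataFrame
    n_points: int
    undefined: list[str]       # constant features, correlations undefined

    def defined_features(self) -> list[str]:
        bad = set(self.undefined)
        return [f for f in self.r.index if f not in bad]


def stage_means(table, metadata: pd.DataFrame, treatment: str) -> pd.DataFrame:
    """Per-feature mean over replicates at each sampled DAS (features x time)."""
    values = table.values if hasattr(table, "state") else table
    ids = metadata.index[metadata["treatment"] == treatment]
    if len(ids) == 0:
        raise ValueError(f"no samples for treatment {treatment!r}")
    sub = values.loc[ids]
    das = metadata.loc[ids, "das"]
    means = sub.groupby(das.values).mean()
    if means.isna().any().any():
        raise ValueError("time point with no observed samples for some feature")
    if means.shape[0] < 3:
        raise ValueError("need >= 3 time points")
    return means.T.sort_index(axis=1)  # features x das


def pairwise_pearson(mean_matrix: pd.DataFrame) -> CorrMatrix:
    """Pearson r over time points for every feature pair, with t-based p."""
    if mean_matrix.shape[1] < 3:
        raise ValueError("need >= 3 columns (time points)")
    n = mean_matrix.shape[1]
    X = mean_matrix.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=0)
    undefined = list(mean_matrix.index[sd == 0])
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.abs(r) >= 1.0] = 0.0
    np.fill_diagonal(p, 0.0)
    idx = mean_matrix.index
    return CorrMatrix(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n_points=n,
        undefined=undefined,
    )


def build_network(corr: CorrMatrix, alpha: float = 0.01) -> nx.Graph:
    """Graph with an edge wherever p <= alpha; isolated nodes retained."""
    g = nx.Graph()
    features = corr.defined_features()
    g.add_nodes_from(corr.r.index)
    rm = corr.r.to_numpy()
    pm = corr.p.to_numpy()
    pos = {f: i for i, f in enumerate(corr.r.index)}
    for a_i, fa in enumerate(features):
        ia = pos[fa]
        for fb in features[a_i + 1 :]:
            ib = pos[fb]
            if pm[ia, ib] <= alpha:
                rv = float(rm[ia, ib])
                g.add_edge(fa, fb, r=rv, p=float(pm[ia, ib]), sign=1 if rv >= 0 else -1)
    return g


def graph_stats(network: nx.Graph) -> dict:
    """Diameter / average path length on the largest component; degrees overall."""
    degrees = dict(network.degree())
    components = list(nx.connected_components(network))
    nontrivial = [c for c in components if len(c) > 1]
    out = {
        "n_nodes": network.number_of_nodes(),
        "n_edges": network.number_of_edges(),
        "n_components": len(components),
        "degree_distribution": dict(
            pd.Series(list(degrees.values())).value_counts().sort_index().astype(int)
        ),
    }
    if network.number_of_edges() == 0:
        out.update({"diameter": None, "avg_path_length": None, "defined": False})
        return out
    giant = network.subgraph(max(nontrivial, key=len))
    out.update(
        {
            "diameter": int(nx.diameter(giant)),
            "avg_path_length": float(nx.average_shortest_path_length(giant)),
            "largest_component_size": giant.number_of_nodes(),
            "defined": True,
        }
    )
    return out


def strong_link_counts(corr: CorrMatrix, threshold: float = 0.7) -> pd.DataFrame:
    """Per feature: number of partners with |r| >= threshold, split by sign."""
    r = corr.r.to_numpy().copy()
    np.fill_diagonal(r, 0.0)
    bad = [corr.r.index.get_loc(f) for f in corr.undefined]
    r[bad, :] = 0.0
    r[:, bad] = 0.0
    pos = np.sum(r >= threshold, axis=1)
    neg = np.sum(r <= -threshold, axis=1)
    return pd.DataFrame(
        {"n_positive": pos, "n_negative": neg, "n_strong": pos + neg},
        index=corr.r.index,
    )


def correlation_of_correlations(corr_A: CorrMatrix, corr_B: CorrMatrix) -> tuple[float, float]:
    """Spearman correlation over the jointly defined upper-triangle pairs."""
    if list(corr_A.r.index) != list(corr_B.r.index):
        raise ValueError("correlation matrices must share the feature universe")
    ok = np.array([f not in set(corr_A.undefined) | set(corr_B.undefined) for f in corr_A.r.index])
    if ok.sum() < 3:
        raise ValueError("no common defined pairs")
    ra = corr_A.r.to_numpy()[np.ix_(ok, ok)]
    rb = corr_B.r.to_numpy()[np.ix_(ok, ok)]
    iu = np.triu_indices(ra.shape[0], k=1)
    rho, p = stats.spearmanr(ra[iu], rb[iu])
    return float(rho), float(p)


def group_correlation_summary(corr: CorrMatrix, groupings: dict[str, list[str]]) -> pd.DataFrame:
    """Within-group pairwise correlation summaries against the background.

    Returns one row per group with the mean/median within-group r and the
    shift = mean(group r) - median(all-pairs r).  Groups with fewer than
    3 usable members are skipped.
    """
    features = corr.defined_features()
    pos = {f: i for i, f in enumerate(corr.r.index)}
    rm = corr.r.to_numpy()
    iu = np.triu_indices(len(corr.r.index), k=1)
    ok = np.array([f in set(features) for f in corr.r.index])
    keep = ok[iu[0]] & ok[iu[1]]
    background = rm[iu][keep]
    bg_median = float(np.median(background))
    rows = []
    for name, members in groupings.items():
        usable = [f for f in members if f in set(features)]
        if len(usable) < 3:
            continue
        idx = np.array([pos[f] for f in usable])
        sub = rm[np.ix_(idx, idx)]
        vals = sub[np.triu_indices(len(idx), k=1)]
        rows.append(
            {
                "group": name,
                "n_members": len(usable),
                "n_pairs": len(vals),
                "mean_r": float(np.mean(vals)),
                "median_r": float(np.median(vals)),
                "background_median": bg_median,
                "shift": float(np.mean(vals)) - bg_median,
            }
        )
    return pd.DataFrame(rows)


def write_graphml(network: nx.Graph, path) -> None:
    """GraphML export for external viewers (Cytoscape, Gephi)."""
    nx.write_graphml(network, path)


def write_edge_list(network: nx.Graph, path) -> None:
    rows = [
        {"source": a, "target": b, "r": d["r"], "p": d["p"], "sign": d["sign"]}
        for a, b, d in sorted(network.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["source", "target", "r", "p", "sign"]).to_csv(
        path, sep="\t", index=False
    )
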
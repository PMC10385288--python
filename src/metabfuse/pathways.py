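"""VIP-driven pathway over-representation and topology impact analysis.

Variables with VIP above a cutoff (conventionally 1) are mapped to
metabolites: overlapped signals (a chemical shift compatible with more than
one metabolite) are dropped, since the responsible metabolite cannot be
determined, and when several unique variables point at the same metabolite
the highest-VIP one represents it. Each pathway in a library (a named
metabolite set with an undirected reaction graph) then gets a right-tail
hypergeometric p-value, a topology impact score (the share of the pathway's
betweenness-centrality mass carried by hit nodes), and a Benjamini-Hochberg
adjusted p-value.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Pathway",
    "PathwayLibrary",
    "select_variables",
    "map_to_metabolites",
    "ora_test",
    "impact_score",
    "adjust_fdr",
    "run_pathway_analysis",
    "make_toy_library",
]


@dataclass
class Pathway:
    name: str
    nodes: set[str]
    edges: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.nodes = set(self.nodes)
        for a, b in self.edges:
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge ({a}, {b}) has an endpoint outside pathway {self.name!r}")

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    @property
    def connected(self) -> bool:
        return nx.is_connected(self.graph()) if self.nodes else False


@dataclass
class PathwayLibrary:
    pathways: list[Pathway]

    @property
    def universe(self) -> set[str]:
        out: set[str] = set()
        for p in self.pathways:
            out |= p.nodes
        return out

    @classmethod
    def from_json(cls, path) -> "PathwayLibrary":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            [
                Pathway(d["name"], set(d["nodes"]), [tuple(e) for e in d.get("edges", [])])
                for d in raw
            ]
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                [
                    {"name": p.name, "nodes": sorted(p.nodes), "edges": [list(e) for e in p.edges]}
                    for p in self.pathways
                ],
                fh,
                indent=1,
            )


def select_variables(model, threshold: float = 1.0) -> list[str]:
    """Variable ids with VIP strictly above the cutoff, descending by VIP."""
    s = model.vip_series()
    sel = s[s > threshold].sort_values(ascending=False)
    return list(sel.index)


def map_to_metabolites(
    selected: list[str],
    vips: pd.Series,
    annotation: dict[str, list[str]],
) -> set[str]:
    """Selected variables -> unique metabolite hit set.

    Variables with multiple candidate metabolites are dropped (overlapped
    signal); among unique-candidate variables sharing a metabolite, the
    highest-VIP variable represents it. Unannotated variables are dropped
    with a warning.
    """
    best: dict[str, tuple[float, str]] = {}
    n_unannotated = 0
    for var in selected:
        cands = annotation.get(var)
        if not cands:
            n_unannotated += 1
            continue
        if len(cands) > 1:
            continue  # ambiguous signal: cannot attribute the change
        m = cands[0]
        v = float(vips[var])
        if m not in best or v > best[m][0]:
            best[m] = (v, var)
    if n_unannotated:
        warnings.warn(f"{n_unannotated} selected variable(s) had no annotation; dropped")
    return set(best)


def ora_test(hits: set[str], pathway_nodes: set[str], universe: set[str]) -> float:
    """Right-tail hypergeometric P(X >= k) over-representation p-value."""
    if not universe:
        raise ValueError("empty universe")
    if not set(hits) <= set(universe):
        raise ValueError("hits must be a subset of the universe")
    M = len(universe)
    K = len(set(pathway_nodes) & set(universe))
    N = len(set(hits) & set(universe))
    k = len(set(hits) & set(pathway_nodes))
    return float(hypergeom.sf(k - 1, M, K, N))


def impact_score(pathway: Pathway, hits: set[str]) -> float:
    """Topology impact in [0, 1]: hit share of betweenness-centrality mass.

    Pathways whose total centrality is zero (single nodes, edgeless or
    star-free graphs with no interior vertices) fall back to uniform mass
    over nodes, so an isolated single-node pathway scores 1 when hit.
    """
    if not pathway.nodes:
        raise ValueError("pathway has no nodes")
    bc = nx.betweenness_centrality(pathway.graph(), normalized=False)
    total = sum(bc.values())
    if total == 0:
        mass = {n: 1.0 / len(pathway.nodes) for n in pathway.nodes}
        total = 1.0
    else:
        mass = bc
    return float(sum(mass[n] for n in pathway.nodes & set(hits)) / total)


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def run_pathway_analysis(
    model,
    annotation: dict[str, list[str]],
    library: PathwayLibrary,
    threshold: float = 1.0,
    alpha: float = 0.05,
    universe: str = "library",
    measured: set[str] | None = None,
) -> tuple[pd.DataFrame, str]:
    """VIP selection -> metabolite mapping -> per-pathway ORA + impact -> FDR.

    ``universe`` is the library's metabolite roster by default, or the
    measured panel with ``universe="measured"``. Pathways with no overlap
    with the universe are excluded. Returns (results sorted by p, status).
    """
    selected = select_variables(model, threshold)
    if not selected:
        return _empty_result(), "no hits: no variable exceeded the VIP threshold"
    vips = model.vip_series()
    hits = map_to_metabolites(selected, vips, annotation)
    if universe == "library":
        uni = library.universe
    elif universe == "measured":
        if measured is None:
            raise ValueError("universe='measured' needs the measured metabolite set")
        uni = set(measured)
    else:
        raise ValueError("universe must be 'library' or 'measured'")
    hits = hits & uni
    if not hits:
        return _empty_result(), "no hits: no selected variable mapped into the universe"
    rows = []
    for pw in library.pathways:
        overlap = pw.nodes & uni
        if not overlap:
            continue
        pw_hits = sorted(pw.nodes & hits)
        p = ora_test(hits, pw.nodes, uni)
        rows.append(
            {
                "pathway": pw.name,
                "hits": len(pw_hits),
                "hit_ids": ";".join(pw_hits),
                "pathway_size": len(overlap),
                "p_value": p,
                "neg_log10_p": -np.log10(p) if p > 0 else np.inf,
                "impact": impact_score(pw, hits),
            }
        )
    res = pd.DataFrame(rows)
    res["fdr_p"] = adjust_fdr(res["p_value"].to_numpy())
    res["significant_fdr"] = res["fdr_p"] < alpha
    res = res.sort_values("p_value", kind="stable").reset_index(drop=True)
    return res, f"{len(hits)} metabolite hits against {len(res)} pathways"


def _empty_result() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "pathway",
            "hits",
            "hit_ids",
            "pathway_size",
            "p_value",
            "neg_log10_p",
            "impact",
            "fdr_p",
            "significant_fdr",
        ]
    )


def make_toy_library(metabolite_ids: list[str], n_pathways: int = 5, seed: int = 0) -> PathwayLibrary:
    """A small synthetic pathway library over the given metabolites.

    Metabolites are dealt round-robin into ``n_pathways`` path-graph
    pathways (chains), a deliberately simple stand-in for curated pathway
    content, which is not shipped.
    """
    rng = np.random.default_rng(seed)
    ids = list(metabolite_ids)
    rng.shuffle(ids)
    groups: list[list[str]] = [[] for _ in range(n_pathways)]
    for i, m in enumerate(ids):
        groups[i % n_pathways].append(m)
    pathways = []
    for g, members in enumerate(groups):
        if not members:
            continue
        edges = [(members[i], members[i + 1]) for i in range(len(members) - 1)]
        pathways.append(Pathway(f"toy_pathway_{g + 1:02d}", set(members), edges))
    return PathwayLibrary(pathways)
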
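"""Module scoring by mean co-alteration weight, and cross-network comparison.

A module's score M is the sum of edge weights over member pairs that are
edges of the weighted network, divided by the number of such induced edges —
i.e. the mean induced edge weight. Module membership itself is a pluggable
input (any external dense-cluster finder); a connected-components fallback
lets the pipeline run without external tools.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import networkx as nx
import pandas as pd
from scipy import stats

from .network_build import WeightedNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModule",
    "module_score",
    "score_modules",
    "compare_module_weights",
    "cutoff_stability",
    "connected_component_detector",
    "read_modules_tsv",
    "write_modules_tsv",
]


@dataclass
class GeneModule:
    """A candidate functional module: an ID and its member gene set."""

    id: int
    members: set[str]

    def __post_init__(self) -> None:
        if len(self.members) < 3:
            raise ValueError(f"module {self.id}: need >= 3 members")


def _induced_weights(module: GeneModule, network: WeightedNetwork) -> list[float]:
    members = sorted(module.members)
    g = network.graph
    return [
        float(g[a][b]["weight"])
        for i, a in enumerate(members)
        for b in members[i + 1 :]
        if g.has_edge(a, b)
    ]


def module_score(module: GeneModule, network: WeightedNetwork) -> float:
    """Mean weight of the module's induced edges.

    Pairs of members that are not network edges contribute nothing; raises
    ``ValueError`` (module unscoreable) when the module induces no edge.
    """
    missing = module.members - set(network.graph.nodes)
    if missing:
        raise ValueError(f"module {module.id}: members absent from network: {sorted(missing)[:5]}")
    weights = _induced_weights(module, network)
    if not weights:
        raise ValueError(f"module {module.id}: no induced edges; unscoreable")
    return sum(weights) / len(weights)


def score_modules(modules: list[GeneModule], network: WeightedNetwork) -> pd.DataFrame:
    """Score table (module_id, N, E, M, rank); unscoreable modules get NaN M."""
    rows = []
    for m in modules:
        weights = (
            _induced_weights(m, network)
            if m.members <= set(network.graph.nodes)
            else []
        )
        rows.append(
            {
                "module_id": m.id,
                "N": len(m.members),
                "E": len(weights),
                "M": sum(weights) / len(weights) if weights else float("nan"),
            }
        )
    df = pd.DataFrame(rows)
    df["rank"] = df["M"].rank(ascending=False, method="min")
    return df.sort_values("module_id").reset_index(drop=True)


def compare_module_weights(
    modules: list[GeneModule], networks: dict[str, WeightedNetwork], reference: str = "ICan"
) -> dict:
    """Pooled induced-edge-weight comparison of the reference vs each baseline.

    The same module membership is evaluated on every network (identical
    skeleton); induced edge weights are pooled per network and a two-sided
    Mann-Whitney test contrasts the reference (ICan) pool against each
    baseline pool. Modules unscoreable in any network are excluded (logged).
    Returns pooled weights, per-module average-weight table, and p-values.
    """
    usable = []
    for m in modules:
        if all(
            m.members <= set(net.graph.nodes) and _induced_weights(m, net)
            for net in networks.values()
        ):
            usable.append(m)
        else:
            logger.info("module %d unscoreable in some network; excluded", m.id)

    pooled = {
        name: [w for m in usable for w in _induced_weights(m, net)]
        for name, net in networks.items()
    }
    per_module = pd.DataFrame(
        {
            "module_id": [m.id for m in usable],
            **{
                name: [module_score(m, net) for m in usable]
                for name, net in networks.items()
            },
        }
    )
    pvals = {}
    ref = pooled[reference]
    for name, weights in pooled.items():
        if name == reference:
            continue
        if ref == weights:
            pvals[name] = 1.0
        else:
            pvals[name] = float(
                stats.mannwhitneyu(ref, weights, alternative="two-sided").pvalue
            )
    return {"pooled": pooled, "per_module": per_module, "pvalues": pvals}


def connected_component_detector(graph: nx.Graph, cutoff: float = 0.0) -> list[set[str]]:
    """Trivial module finder: connected components with >= 3 nodes.

    The cutoff argument exists for interface compatibility with density-based
    finders and is ignored.
    """
    return [set(c) for c in nx.connected_components(graph) if len(c) >= 3]


def cutoff_stability(
    detector,
    skeleton: nx.Graph,
    cutoffs: tuple[float, ...] = (0.01, 0.02, 0.03, 0.04, 0.05),
    reference_cutoff: float | None = None,
) -> pd.DataFrame:
    """Cluster-size deviation of detected modules across detector cutoffs.

    The detector runs on the unweighted skeleton at each cutoff; modules found
    at the reference cutoff (default: the middle of ``cutoffs``) are matched
    to the best-Jaccard module at every other cutoff. The output has one row
    per reference module with its matched size per cutoff and the standard
    deviation of those sizes ("deviation"); a cutoff where the detector finds
    nothing is recorded as missing.
    """
    cutoffs = tuple(cutoffs)
    if reference_cutoff is None:
        reference_cutoff = cutoffs[len(cutoffs) // 2]
    found = {c: detector(skeleton, c) for c in cutoffs}
    reference = found[reference_cutoff]
    rows = []
    for mid, ref_mod in enumerate(reference):
        row: dict = {"module_id": mid, "reference_size": len(ref_mod)}
        sizes = []
        for c in cutoffs:
            candidates = found[c]
            if not candidates:
                row[f"size_at_{c}"] = float("nan")
                continue
            best = max(
                candidates, key=lambda m: len(m & ref_mod) / len(m | ref_mod)
            )
            row[f"size_at_{c}"] = len(best)
            sizes.append(len(best))
        row["deviation"] = float(pd.Series(sizes, dtype=float).std(ddof=0)) if sizes else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def read_modules_tsv(path: str | os.PathLike) -> list[GeneModule]:
    """Read 'module_id<TAB>gene' membership (header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["module_id", "gene"], dtype=str)
    if df.iloc[0, 0] == "module_id":
        df = df.iloc[1:]
    out = []
    for mid, group in df.groupby("module_id", sort=True):
        out.append(GeneModule(id=int(mid), members=set(group["gene"])))
    return out


def write_modules_tsv(modules: list[GeneModule], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("module_id\tgene\n")
        for m in modules:
            for gene in sorted(m.members):
                fh.write(f"{m.id}\t{gene}\n")
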
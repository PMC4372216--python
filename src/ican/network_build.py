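"""Assemble the integrated co-alteration network (ICan) and baselines.

ICan restricts the Human Background Network to genes present in all three
omics layers and weights every surviving edge with the CCA-based omega.
Baselines GCE/GCC/GCM use the same skeleton with absolute Pearson weights
from one layer (expression, copy number, methylation respectively), so the
four networks differ only in edge weight.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .cca import pair_cca_result, pearson_weight
from .network_io import BackgroundNetwork
from .omics import OmicsProfiles

logger = logging.getLogger(__name__)

__all__ = [
    "WeightedNetwork",
    "build_ican",
    "build_single_level",
    "degree_summary",
    "LAYER_TAGS",
]

LAYER_TAGS = {"expression": "GCE", "copy_number": "GCC", "methylation": "GCM"}


@dataclass
class WeightedNetwork:
    """Undirected graph over profiled genes with per-edge weight in [0, 1]."""

    graph: nx.Graph
    method: str = "ICan"
    extra: dict = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def weight(self, a: str, b: str) -> float:
        return float(self.graph[a][b]["weight"])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a, b, data in self.graph.edges(data=True):
            x, y = sorted((a, b))
            row = {"gene_a": x, "gene_b": y, "weight": data["weight"]}
            for key in ("lambda1", "lambda2", "lambda3", "p1", "p2", "p3"):
                if key in data:
                    row[key] = data[key]
            rows.append(row)
        return pd.DataFrame(rows).sort_values(["gene_a", "gene_b"]).reset_index(drop=True)

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike, method: str = "ICan") -> "WeightedNetwork":
        df = pd.read_csv(path, sep="\t")
        g = nx.Graph()
        for row in df.itertuples(index=False):
            g.add_edge(row.gene_a, row.gene_b, weight=float(row.weight))
        return cls(graph=g, method=method)


def _profiled_skeleton(
    hbn: BackgroundNetwork, profiles: OmicsProfiles
) -> list[tuple[str, str]]:
    profiled = set(profiles.genes)
    edges = [
        tuple(sorted((a, b)))
        for a, b in hbn.graph.edges
        if a in profiled and b in profiled
    ]
    if not edges:
        raise ValueError(
            "no background edge has both endpoints profiled "
            f"(HBN nodes: {hbn.n_nodes}, profiled genes: {len(profiled)})"
        )
    return edges


def build_ican(
    hbn: BackgroundNetwork,
    profiles: OmicsProfiles,
    alpha: float = 0.05,
    weight_basis: str = "lambda",
    bartlett_form: str = "printed",
) -> WeightedNetwork:
    """Weight the profiled HBN skeleton with the CCA co-alteration omega.

    Genes absent from any omics layer are removed; each surviving edge gets
    omega from the pairwise CCA of the two genes' 3 x n profiles. Edges whose
    CCA fails numerically (both genes constant in every layer) are dropped
    with a logged count; isolated nodes are dropped.
    """
    g = nx.Graph()
    blocks = {gene: profiles.gene_block(gene) for gene in profiles.genes}
    n_failed = 0
    for a, b in _profiled_skeleton(hbn, profiles):
        try:
            res = pair_cca_result(
                blocks[a],
                blocks[b],
                alpha=alpha,
                weight_basis=weight_basis,
                bartlett_form=bartlett_form,
            )
        except ValueError:
            n_failed += 1
            continue
        g.add_edge(
            a,
            b,
            weight=res.omega,
            lambda1=res.lambdas[0],
            lambda2=res.lambdas[1],
            lambda3=res.lambdas[2],
            p1=res.pvals[0],
            p2=res.pvals[1],
            p3=res.pvals[2],
        )
    if n_failed:
        logger.warning("dropped %d edges with degenerate CCA", n_failed)
    return WeightedNetwork(graph=g, method="ICan", extra={"failed_edges": n_failed})


def build_single_level(
    hbn: BackgroundNetwork, profiles: OmicsProfiles, layer: str
) -> WeightedNetwork:
    """Baseline network with absolute Pearson weights from a single layer."""
    if layer not in LAYER_TAGS:
        raise ValueError(f"unknown layer {layer!r}; expected one of {sorted(LAYER_TAGS)}")
    mat = profiles.layer(layer)
    idx = {gene: i for i, gene in enumerate(profiles.genes)}
    g = nx.Graph()
    n_failed = 0
    for a, b in _profiled_skeleton(hbn, profiles):
        try:
            w, signed = pearson_weight(mat[idx[a]], mat[idx[b]])
        except ValueError:
            n_failed += 1
            continue
        g.add_edge(a, b, weight=w, signed_r=signed)
    if n_failed:
        logger.warning("dropped %d degenerate edges in %s", n_failed, LAYER_TAGS[layer])
    return WeightedNetwork(
        graph=g, method=LAYER_TAGS[layer], extra={"failed_edges": n_failed}
    )


def degree_summary(network: WeightedNetwork) -> dict:
    """Per-node degree table plus a log-log power-law tail diagnostic.

    The diagnostic is the least-squares slope of log10 complementary CDF
    against log10 degree (positive degrees only) — a descriptive check of
    heavy-tailedness, not a hypothesis test.
    """
    if network.n_nodes < 10:
        raise ValueError("degree_summary requires >= 10 nodes")
    degrees = pd.Series(dict(network.graph.degree()), name="degree").sort_index()
    pos = np.sort(degrees[degrees > 0].to_numpy())
    uniq = np.unique(pos)
    ccdf = np.array([(pos >= d).mean() for d in uniq])
    slope = float("nan")
    if len(uniq) >= 3:
        slope = float(np.polyfit(np.log10(uniq), np.log10(ccdf), 1)[0])
    return {
        "degrees": degrees,
        "mean_degree": float(degrees.mean()),
        "max_degree": int(degrees.max()),
        "ccdf_slope": slope,
    }
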
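"""Synthetic fixtures: multi-omics profiles with planted cross-gene
co-alteration, scale-free background networks with a planted disease module,
and survival cohorts with planted hazard effects.

The multi-omics generator uses a latent-factor construction: every layer of a
gene is alpha * z + sqrt(1 - alpha^2) * noise, where genes of a planted pair
share the latent factor z. With equal loadings across the three layers the
population first canonical correlation between two planted genes is

    rho_1 = 3 alpha^2 / (1 + 2 alpha^2),

which inverts in closed form to alpha^2 = r / (3 - 2 r) for a target r < 1.
Methylation is squashed into [0, 1] by a logistic map (near-linear in the
bulk, so the planted correlation survives discretization of the scale), and
discrete copy-number calls derive from the continuous layer by symmetric
quantile thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .network_io import BackgroundNetwork
from .omics import AlterationCalls, OmicsProfiles
from .survival import ClinicalTable

__all__ = [
    "SyntheticTruth",
    "generate_multiomics",
    "generate_network",
    "generate_survival",
]


@dataclass
class SyntheticTruth:
    """Ground truth planted by a generator (pairs, module, seeds, hazards)."""

    planted_pairs: list[tuple[tuple[str, str], float]] = field(default_factory=list)
    module_members: set[str] = field(default_factory=set)
    seed_genes: set[str] = field(default_factory=set)
    planted_hazards: list[tuple[str, str, float]] = field(default_factory=list)
    rng_seed: int | None = None


def _loading_for_target(r: float) -> float:
    """Per-layer latent loading giving population canonical correlation r."""
    if not 0 <= r < 1:
        raise ValueError("target canonical correlation must lie in [0, 1)")
    return float(np.sqrt(r / (3 - 2 * r)))


def generate_multiomics(
    n_genes: int = 50,
    n_samples: int = 200,
    planted_pairs: list[tuple[tuple[str, str], float]] | None = None,
    noise_sd: float = 1.0,
    rng: np.random.Generator | int | None = None,
    genes: list[str] | None = None,
    expr_location: float = 8.0,
    expr_scale: float = 2.0,
    amp_quantile: float = 0.90,
    homdel_quantile: float = 0.02,
) -> tuple[OmicsProfiles, SyntheticTruth]:
    """Matched three-layer profiles with controllable cross-gene correlation.

    Each planted pair ((gene_a, gene_b), r) shares one latent factor across
    all three layers of both genes, with the loading set so the population
    first canonical correlation equals r; all other genes are independent.
    Expression is an affine transform of the latent scale, methylation a
    logistic squash into [0, 1], and discrete copy-number calls come from
    quantile thresholds of the continuous layer (calls 2/-2 at the outer
    halves of the amplified/deleted tails). Deterministic for a fixed rng.
    """
    if n_samples < 10:
        raise ValueError("need at least 10 samples")
    rng = np.random.default_rng(rng)
    if genes is None:
        genes = [f"G{i:04d}" for i in range(n_genes)]
    n_genes = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    planted_pairs = list(planted_pairs or [])

    # latent value per gene per layer, standard normal
    latent = rng.standard_normal((n_genes, 3, n_samples)) * noise_sd
    for (a, b), r in planted_pairs:
        alpha = _loading_for_target(r)
        z = rng.standard_normal(n_samples)
        for g in (a, b):
            i = gene_pos[g]
            noise = rng.standard_normal((3, n_samples))
            latent[i] = (alpha * z + np.sqrt(1 - alpha**2) * noise) * noise_sd

    expr = expr_location + expr_scale * latent[:, 0, :]
    cn = latent[:, 1, :]
    meth = 1.0 / (1.0 + np.exp(-latent[:, 2, :]))

    calls = np.zeros_like(cn, dtype=int)
    lo = np.quantile(cn, homdel_quantile, axis=1, keepdims=True)
    lo_half = np.quantile(cn, homdel_quantile / 2, axis=1, keepdims=True)
    hi = np.quantile(cn, amp_quantile, axis=1, keepdims=True)
    hi_half = np.quantile(cn, (1 + amp_quantile) / 2, axis=1, keepdims=True)
    calls[cn < lo] = -1
    calls[cn < lo_half] = -2
    calls[cn > hi] = 1
    calls[cn > hi_half] = 2

    profiles = OmicsProfiles(
        genes=list(genes),
        samples=[f"S{j:04d}" for j in range(n_samples)],
        expression=expr,
        copy_number=cn,
        methylation=meth,
        cn_calls=calls,
    )
    truth = SyntheticTruth(planted_pairs=planted_pairs)
    return profiles, truth


def generate_network(
    n_genes: int = 500,
    attachment: int = 2,
    module_size: int = 40,
    seeds_fraction: float = 0.5,
    module_density: float = 0.6,
    rng: np.random.Generator | int | None = None,
) -> tuple[BackgroundNetwork, SyntheticTruth]:
    """Scale-free background graph with a planted seed-adjacent disease module.

    A preferential-attachment (Barabasi-Albert) graph over ``n_genes`` genes;
    ``module_size`` randomly chosen nodes are densified into a clique-like
    module (each member pair wired with probability ``module_density``), and
    a random ``seeds_fraction`` of the module is designated as the seed set.
    ``module_size = 0`` yields the plain preferential-attachment graph.
    """
    rng = np.random.default_rng(rng)
    ba_seed = int(rng.integers(0, 2**31 - 1))
    g = nx.barabasi_albert_graph(n_genes, attachment, seed=ba_seed)
    names = {i: f"G{i:04d}" for i in g.nodes}
    g = nx.relabel_nodes(g, names)

    truth = SyntheticTruth()
    if module_size > 0:
        members = sorted(
            rng.choice(sorted(g.nodes), size=module_size, replace=False).tolist()
        )
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                if rng.random() < module_density:
                    g.add_edge(a, b)
        n_seeds = max(1, int(round(seeds_fraction * module_size)))
        truth.module_members = set(members)
        truth.seed_genes = set(rng.choice(members, size=n_seeds, replace=False).tolist())
    return BackgroundNetwork(graph=g), truth


def generate_survival(
    n_samples: int = 300,
    baseline_hazard: float = 1 / 1000,
    planted: list[tuple[str, str, float]] | None = None,
    censoring_rate: float = 0.3,
    calls: AlterationCalls | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[ClinicalTable, SyntheticTruth]:
    """Exponential survival times with planted per-feature hazard ratios.

    Each sample's hazard is the baseline times the product of hazard ratios
    of the planted (gene, feature, HR) triples it carries (per ``calls``).
    Censoring is independent exponential with rate tuned so that roughly
    ``censoring_rate`` of subjects are censored under the baseline hazard.
    """
    rng = np.random.default_rng(rng)
    planted = list(planted or [])
    if calls is not None:
        samples = list(calls.samples)[:n_samples]
    else:
        samples = [f"S{j:04d}" for j in range(n_samples)]
    n = len(samples)

    hazards = np.full(n, baseline_hazard, dtype=float)
    for gene, feature, hr in planted:
        if calls is None:
            raise ValueError("planted hazards require alteration calls")
        gi = calls.genes.index(gene)
        carrier = calls.feature(feature)[gi, : len(samples)]
        hazards[carrier] *= hr

    event_times = rng.exponential(1.0 / hazards)
    # censoring rate c/(c+h) = target  =>  c = h * target / (1 - target)
    c_rate = baseline_hazard * censoring_rate / max(1e-12, 1 - censoring_rate)
    censor_times = (
        rng.exponential(1.0 / c_rate, size=n) if c_rate > 0 else np.full(n, np.inf)
    )
    times = np.minimum(event_times, censor_times)
    events = (event_times <= censor_times).astype(int)
    times = np.maximum(times, 1e-6)
    clinical = ClinicalTable(samples=samples, times=times, events=events)
    truth = SyntheticTruth(planted_hazards=planted)
    return clinical, truth
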
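"""Aligned three-layer omics profiles and alteration discretization.

An :class:`OmicsProfiles` holds gene-level expression, continuous copy number
and promoter-methylation beta values over a shared gene and sample ordering,
optionally with discrete GISTIC-style copy-number calls in {-2,-1,0,1,2}.

Discretization follows oncogene/tumor-suppressor logic: amplification (call
1/2), homozygous deletion (call -2), over/under-expression beyond one standard
deviation from the per-gene mean, and hypo-/hyper-methylation at beta < 0.2 /
beta > 0.8. Boundary ties fall in the unaltered class (strict inequalities).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OmicsProfiles",
    "AlterationCalls",
    "ALTERATION_FEATURES",
    "collapse_probes",
    "knn_impute",
    "discretize",
]

ALTERATION_FEATURES = (
    "amplified",
    "homdel",
    "overexpressed",
    "underexpressed",
    "hypomethylated",
    "hypermethylated",
)


@dataclass
class OmicsProfiles:
    """Gene x sample matrices for expression, copy number and methylation.

    All three share row (gene) and column (sample) ordering; methylation beta
    values lie in [0, 1]; matrices are complete (impute first).
    """

    genes: list[str]
    samples: list[str]
    expression: np.ndarray
    copy_number: np.ndarray
    methylation: np.ndarray
    cn_calls: np.ndarray | None = None

    def __post_init__(self) -> None:
        shape = (len(self.genes), len(self.samples))
        for name in ("expression", "copy_number", "methylation"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != shape:
                raise ValueError(f"{name} has shape {m.shape}, expected {shape}")
            if np.isnan(m).any():
                raise ValueError(f"{name} contains missing values; impute first")
            setattr(self, name, m)
        if self.methylation.size and (
            self.methylation.min() < 0 or self.methylation.max() > 1
        ):
            raise ValueError("methylation beta values must lie in [0, 1]")
        if self.cn_calls is not None:
            calls = np.asarray(self.cn_calls)
            if calls.shape != shape:
                raise ValueError("cn_calls shape mismatch")
            if not np.isin(calls, [-2, -1, 0, 1, 2]).all():
                raise ValueError("cn_calls must be integers in {-2,-1,0,1,2}")
            self.cn_calls = calls.astype(int)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def gene_index(self, gene: str) -> int:
        return self.genes.index(gene)

    def layer(self, name: str) -> np.ndarray:
        """Return one layer by its canonical name."""
        try:
            return {
                "expression": self.expression,
                "copy_number": self.copy_number,
                "methylation": self.methylation,
            }[name]
        except KeyError:
            raise ValueError(
                f"unknown layer {name!r}; expected expression, copy_number "
                "or methylation"
            ) from None

    def gene_block(self, gene: str) -> np.ndarray:
        """The 3 x n_samples profile (expression, CN, methylation) of one gene."""
        i = self.gene_index(gene)
        return np.vstack(
            [self.expression[i], self.copy_number[i], self.methylation[i]]
        )

    def subset_samples(self, sample_ids: list[str]) -> "OmicsProfiles":
        idx = [self.samples.index(s) for s in sample_ids]
        return OmicsProfiles(
            genes=list(self.genes),
            samples=list(sample_ids),
            expression=self.expression[:, idx],
            copy_number=self.copy_number[:, idx],
            methylation=self.methylation[:, idx],
            cn_calls=None if self.cn_calls is None else self.cn_calls[:, idx],
        )

    def to_dir(self, outdir: str | os.PathLike) -> None:
        """Write the bundle as per-layer TSVs (genes in rows)."""
        os.makedirs(outdir, exist_ok=True)
        for name in ("expression", "copy_number", "methylation"):
            pd.DataFrame(
                getattr(self, name), index=self.genes, columns=self.samples
            ).to_csv(os.path.join(outdir, f"{name}.tsv"), sep="\t")
        if self.cn_calls is not None:
            pd.DataFrame(
                self.cn_calls, index=self.genes, columns=self.samples
            ).to_csv(os.path.join(outdir, "cn_calls.tsv"), sep="\t")

    @classmethod
    def from_dir(cls, indir: str | os.PathLike) -> "OmicsProfiles":
        def load(name: str) -> pd.DataFrame:
            return pd.read_csv(os.path.join(indir, f"{name}.tsv"), sep="\t", index_col=0)

        expr = load("expression")
        cn = load("copy_number").reindex(index=expr.index, columns=expr.columns)
        meth = load("methylation").reindex(index=expr.index, columns=expr.columns)
        calls_path = os.path.join(indir, "cn_calls.tsv")
        calls = None
        if os.path.exists(calls_path):
            calls = (
                pd.read_csv(calls_path, sep="\t", index_col=0)
                .reindex(index=expr.index, columns=expr.columns)
                .to_numpy()
            )
        return cls(
            genes=list(expr.index),
            samples=list(expr.columns),
            expression=expr.to_numpy(),
            copy_number=cn.to_numpy(),
            methylation=meth.to_numpy(),
            cn_calls=calls,
        )


@dataclass
class AlterationCalls:
    """Six binary alteration features per gene x sample.

    ``features[name]`` is a boolean genes x samples matrix; hypo- and
    hyper-methylation are mutually exclusive, as are over- and
    under-expression.
    """

    genes: list[str]
    samples: list[str]
    features: dict[str, np.ndarray] = field(default_factory=dict)

    def feature(self, name: str) -> np.ndarray:
        return self.features[name]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: gene, sample, feature, altered (only True rows)."""
        rows = []
        for name, mat in self.features.items():
            gi, si = np.nonzero(mat)
            for g, s in zip(gi, si):
                rows.append((self.genes[g], self.samples[s], name))
        return pd.DataFrame(rows, columns=["gene", "sample", "feature"])


def collapse_probes(
    probe_matrix: pd.DataFrame, probe_to_gene: dict[str, str]
) -> pd.DataFrame:
    """Average probe-level rows into gene-level rows.

    Probes absent from the map, mapped to an empty symbol, or entirely missing
    are dropped before averaging; per gene the value is the arithmetic mean of
    its surviving probes, computed per sample over observed values.
    """
    genes = probe_matrix.index.to_series().map(probe_to_gene)
    keep = genes.notna() & (genes != "")
    keep &= probe_matrix.notna().any(axis=1)
    kept = probe_matrix.loc[keep]
    if kept.empty:
        return pd.DataFrame(columns=probe_matrix.columns)
    return kept.groupby(genes[keep]).mean()


def knn_impute(matrix: np.ndarray, k: int = 10, min_overlap: int = 3) -> np.ndarray:
    """Fill missing entries from the k nearest rows.

    The distance between two rows is the Euclidean distance over their
    mutually observed columns; a candidate neighbor is skipped when fewer than
    ``min_overlap`` columns are shared or when it lacks the target column.
    The imputed value is the mean of the k nearest usable neighbors' values in
    that column. Rows with no observed entries are dropped (logged).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x = np.array(matrix, dtype=float)
    if np.isnan(x).all():
        raise ValueError("matrix is entirely missing")
    observed = ~np.isnan(x)
    empty_rows = ~observed.any(axis=1)
    if empty_rows.any():
        logger.warning("dropping %d rows with no observed entries", empty_rows.sum())
        x = x[~empty_rows]
        observed = observed[~empty_rows]
    out = x.copy()
    for i in np.nonzero(~observed.all(axis=1))[0]:
        missing_cols = np.nonzero(~observed[i])[0]
        # distance from row i to every other row over shared columns
        dists = np.full(x.shape[0], np.inf)
        for j in range(x.shape[0]):
            if j == i:
                continue
            shared = observed[i] & observed[j]
            if shared.sum() < min_overlap:
                continue
            diff = x[i, shared] - x[j, shared]
            dists[j] = float(np.sqrt(np.sum(diff * diff)))
        order = np.argsort(dists, kind="stable")
        for s in missing_cols:
            donors = [j for j in order if np.isfinite(dists[j]) and observed[j, s]]
            if not donors:
                # fall back to the column mean of observed values
                col = x[observed[:, s], s]
                out[i, s] = float(col.mean())
                continue
            out[i, s] = float(x[donors[:k], s].mean())
    return out


def discretize(
    profiles: OmicsProfiles,
    tumor_samples: list[str] | None = None,
    beta_low: float = 0.2,
    beta_high: float = 0.8,
    ddof: int = 1,
) -> AlterationCalls:
    """Call the six binary alteration features per gene and sample.

    amplified: CN call in {1, 2}; homdel: CN call == -2;
    over/under-expressed: expression strictly beyond mean +/- SD, with the
    per-gene mean and sample SD taken over ``tumor_samples`` (default: all
    samples in the profiles); hypo-/hyper-methylated: beta strictly below
    ``beta_low`` / above ``beta_high``. Zero-variance expression genes get no
    expression calls (logged).
    """
    if profiles.cn_calls is None:
        raise ValueError("discretize requires discrete copy-number calls")
    if tumor_samples is None:
        stat_idx = np.arange(profiles.n_samples)
    else:
        stat_idx = np.array([profiles.samples.index(s) for s in tumor_samples])

    expr = profiles.expression
    mu = expr[:, stat_idx].mean(axis=1, keepdims=True)
    sd = expr[:, stat_idx].std(axis=1, ddof=ddof, keepdims=True)
    flat = (sd[:, 0] == 0)
    if flat.any():
        logger.info(
            "%d genes with zero expression variance get no expression calls",
            int(flat.sum()),
        )
    nonflat = ~flat[:, None]

    calls = profiles.cn_calls
    features = {
        "amplified": np.isin(calls, [1, 2]),
        "homdel": calls == -2,
        "overexpressed": (expr > mu + sd) & nonflat,
        "underexpressed": (expr < mu - sd) & nonflat,
        "hypomethylated": profiles.methylation < beta_low,
        "hypermethylated": profiles.methylation > beta_high,
    }
    return AlterationCalls(
        genes=list(profiles.genes), samples=list(profiles.samples), features=features
    )
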
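"""Kaplan-Meier estimation and log-rank screening of alteration features.

For each candidate gene and each of the six binary alteration features
(amplified, homozygously deleted, over-/under-expressed, hypo-/hyper-
methylated), samples are split by feature presence and the two survival
curves compared by the log-rank test. Benjamini-Hochberg adjustment runs
across all actually tested (gene, feature) pairs; a feature is flagged
significant when p < 0.05 and FDR < 0.25, with a risk/protective label from
which group's curve sits lower.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from statsmodels.stats.multitest import multipletests

from .omics import ALTERATION_FEATURES, AlterationCalls

logger = logging.getLogger(__name__)

__all__ = [
    "ClinicalTable",
    "km_estimate",
    "logrank_test",
    "screen_survival_features",
]


@dataclass
class ClinicalTable:
    """Per-sample survival time (days, > 0) and event indicator (1 = death)."""

    samples: list[str]
    times: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        if len(self.samples) != len(self.times) or len(self.times) != len(self.events):
            raise ValueError("samples, times and events must be equal length")
        if (self.times <= 0).any():
            raise ValueError("survival times must be positive")
        if not np.isin(self.events, [0, 1]).all():
            raise ValueError("event indicator must be 0/1")

    def __len__(self) -> int:
        return len(self.samples)

    def subset(self, mask: np.ndarray) -> "ClinicalTable":
        mask = np.asarray(mask, dtype=bool)
        return ClinicalTable(
            samples=[s for s, m in zip(self.samples, mask) if m],
            times=self.times[mask],
            events=self.events[mask],
        )

    def to_tsv(self, path: str | os.PathLike) -> None:
        pd.DataFrame(
            {"sample_id": self.samples, "time_days": self.times, "event": self.events}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "ClinicalTable":
        df = pd.read_csv(path, sep="\t")
        return cls(
            samples=df["sample_id"].astype(str).tolist(),
            times=df["time_days"].to_numpy(),
            events=df["event"].to_numpy(),
        )


def km_estimate(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    """Product-limit survival estimate S(t) = prod(1 - d_i/n_i).

    Returns a step table (time, at_risk, observed, survival). Events at a
    tied event/censoring time are processed first (standard convention).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("km_estimate requires at least one subject")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame(
        {
            "time": table.index.to_numpy(dtype=float),
            "at_risk": table["at_risk"].to_numpy(),
            "observed": table["observed"].to_numpy(),
            "survival": surv.reindex(table.index).to_numpy(),
        }
    )
    return out.reset_index(drop=True)


def logrank_test(group_a: ClinicalTable, group_b: ClinicalTable) -> tuple[float, float]:
    """Two-group log-rank chi-squared statistic (1 df) and p-value.

    Zero events overall yields (0, 1) with a logged flag.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    if group_a.events.sum() + group_b.events.sum() == 0:
        logger.info("log-rank with zero events: p = 1")
        return 0.0, 1.0
    res = _ll_logrank(
        group_a.times, group_b.times, event_observed_A=group_a.events,
        event_observed_B=group_b.events,
    )
    return float(res.test_statistic), float(res.p_value)


def _restricted_mean(times: np.ndarray, events: np.ndarray, horizon: float) -> float:
    """Area under the KM curve up to ``horizon`` (restricted mean survival)."""
    km = km_estimate(times, events)
    grid_t = [0.0]
    grid_s = [1.0]
    for t, s in zip(km["time"], km["survival"]):
        if t > horizon:
            break
        grid_t.append(float(t))
        grid_s.append(float(s))
    grid_t.append(horizon)
    area = 0.0
    for i in range(1, len(grid_t)):
        area += grid_s[i - 1] * (grid_t[i] - grid_t[i - 1])
    return area


def screen_survival_features(
    calls: AlterationCalls,
    clinical: ClinicalTable,
    genes: list[str] | set[str],
    p_max: float = 0.05,
    fdr_max: float = 0.25,
    min_group: int = 5,
) -> pd.DataFrame:
    """Log-rank screen of every (candidate gene, alteration feature) pair.

    Samples shared between calls and clinical are split by feature presence;
    features with fewer than ``min_group`` positive samples (or no negatives)
    are skipped. BH adjustment runs over the tested pairs only; significant
    <=> p < ``p_max`` and q < ``fdr_max``. Direction is "risk" when the
    feature-positive group's restricted mean survival is lower.
    """
    shared = [s for s in clinical.samples if s in set(calls.samples)]
    if not shared:
        raise ValueError("no samples shared between alteration calls and clinical data")
    call_idx = {s: i for i, s in enumerate(calls.samples)}
    clin_mask = np.array([s in set(shared) for s in clinical.samples])
    clin = clinical.subset(clin_mask)
    cols = np.array([call_idx[s] for s in clin.samples])
    gene_set = [g for g in genes if g in set(calls.genes)]
    gene_idx = {g: i for i, g in enumerate(calls.genes)}

    rows = []
    for gene in gene_set:
        gi = gene_idx[gene]
        for feature in ALTERATION_FEATURES:
            pos = calls.feature(feature)[gi, cols]
            n_pos = int(pos.sum())
            n_neg = int((~pos).sum())
            if n_pos < min_group or n_neg == 0:
                logger.debug("skipping %s/%s: %d positives", gene, feature, n_pos)
                continue
            ga, gb = clin.subset(pos), clin.subset(~pos)
            stat, p = logrank_test(ga, gb)
            horizon = float(min(ga.times.max(), gb.times.max()))
            direction = (
                "risk"
                if _restricted_mean(ga.times, ga.events, horizon)
                < _restricted_mean(gb.times, gb.events, horizon)
                else "protective"
            )
            rows.append(
                {
                    "gene": gene,
                    "feature": feature,
                    "nA": n_pos,
                    "nB": n_neg,
                    "logrank_stat": stat,
                    "p": p,
                    "direction": direction,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=["gene", "feature", "nA", "nB", "logrank_stat", "p", "direction"],
    )
    if out.empty:
        out["q"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
        return out
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["significant"] = (out["p"] < p_max) & (out["q"] < fdr_max)
    return out[
        ["gene", "feature", "nA", "nB", "logrank_stat", "p", "q", "direction", "significant"]
    ]
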
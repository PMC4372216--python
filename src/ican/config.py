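"""Run configuration with the framework's documented default parameters."""

from __future__ import annotations

import os
from dataclasses import dataclass, field, fields

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All tunable parameters of the pipeline, with their default values.

    Defaults: restart probability 0.7, RWR L1 tolerance 1e-10, 1000 seed
    permutations, expression fold-change 2 at FDR 0.05, methylation FDR 0.005,
    methylation beta cutoffs 0.2/0.8, survival cutoffs p 0.05 and FDR 0.25,
    top fraction 0.2 for alteration categories, and a recorded density-based
    module-finder cutoff of 0.02 (provenance only; module membership is a
    pluggable input).
    """

    # inputs / outputs
    profiles_dir: str = ""
    hbn_path: str = ""
    seeds_path: str = ""
    clinical_path: str = ""
    modules_path: str = ""
    normal_dir: str = ""  # optional normal-cohort profiles for the diff stage
    outdir: str = "ican_out"

    # random walk
    restart: float = 0.7
    tol: float = 1e-10
    n_perm: int = 1000

    # CCA weighting
    alpha: float = 0.05
    weight_basis: str = "lambda"
    bartlett_form: str = "printed"

    # differential analysis
    fc_min: float = 2.0
    expr_fdr: float = 0.05
    meth_fdr: float = 0.005

    # discretization
    beta_low: float = 0.2
    beta_high: float = 0.8

    # survival screen
    surv_p: float = 0.05
    surv_fdr: float = 0.25
    min_group: int = 5

    # misc
    top_fraction: float = 0.2
    module_cutoff: float = 0.02
    folds: int = 5
    rng_seed: int = 0

    def validate(self) -> None:
        checks = {
            "restart": 0 < self.restart <= 1,
            "tol": self.tol > 0,
            "n_perm": self.n_perm >= 1,
            "alpha": 0 < self.alpha < 1,
            "fc_min": self.fc_min >= 1,
            "expr_fdr": 0 < self.expr_fdr < 1,
            "meth_fdr": 0 < self.meth_fdr < 1,
            "beta_low": 0 < self.beta_low < self.beta_high,
            "beta_high": self.beta_high < 1,
            "surv_p": 0 < self.surv_p < 1,
            "surv_fdr": 0 < self.surv_fdr < 1,
            "top_fraction": 0 < self.top_fraction <= 1,
            "folds": self.folds >= 2,
            "weight_basis": self.weight_basis in {"lambda", "rho"},
            "bartlett_form": self.bartlett_form in {"printed", "standard"},
        }
        bad = [k for k, ok in checks.items() if not ok]
        if bad:
            raise ValueError(f"invalid configuration values: {bad}")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "RunConfig":
        """Read a flat key=value config file (lines starting with # ignored)."""
        kwargs: dict = {}
        types = {f.name: f.type for f in fields(cls)}
        defaults = cls()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key not in types:
                    raise ValueError(f"unknown config key {key!r}")
                current = getattr(defaults, key)
                if isinstance(current, bool):
                    kwargs[key] = value.lower() in {"1", "true", "yes"}
                elif isinstance(current, int):
                    kwargs[key] = int(value)
                elif isinstance(current, float):
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = value
        return cls(**kwargs)
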
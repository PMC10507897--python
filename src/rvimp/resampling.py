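"""Residual-VIMP comparison and the subsampling hypothesis tests.

Two forests are compared for a designated feature of interest Z:

* model A — the original forest on (X_{-p}, Z); its permutation
  importance VIMP_A(Z) measures Z's marginal contribution.
* model B — the adjusted forest on (X_{-p}, eps_Z) where Z is replaced
  by its residuals after regressing Z on the other predictors;
  VIMP_B(eps_Z) measures the contribution of the part of Z the other
  predictors cannot explain.

Hypotheses (both one-sided):

* H0(1): VIMP_A(Z) = VIMP_B(eps_Z) — none of Z's importance is borrowed
  from correlated predictors; rejected when VIMP_A(Z) exceeds the
  empirical (1 - alpha)-quantile of the subsample distribution of
  VIMP_B(eps_Z).
* H0(2): VIMP_B(eps_Z) = 0 — the residual information is useless for
  prediction; rejected when the alpha-quantile of that distribution
  exceeds 0.

The subsample distribution is built from ``m`` draws of 63.2% of the
rows without replacement (the 0.632-rule: each row's inclusion
probability matches a size-n bootstrap, while avoiding duplicates that
would leak training rows into out-of-bag sets).  Within every draw the
residual model g is refitted on exactly the drawn rows and a fresh
forest is trained on them.  Because VIMPs at subsample size 0.632 n are
systematically attenuated relative to the full sample, the m values are
mean-shifted so that their average equals the full-sample VIMP_B(eps_Z)
before any quantile is read off.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datasets import TabularDataset
from .forest import ForestSpec, VimpVector, all_vimps, permutation_vimp, train_forest
from .residualize import ResidualModelSpec, fit_g, residuals

__all__ = [
    "RvimpConfig",
    "RvimpResult",
    "draw_subsample",
    "empirical_quantile",
    "vimp_model_a",
    "vimp_model_b",
    "run_rvimp",
]

RESIDUAL_SUFFIX = "_resid"


@dataclass(frozen=True)
class RvimpConfig:
    """Configuration of one residual-VIMP test run."""

    z_column: str = "Z"
    m: int = 100
    subsample_fraction: float = 0.632
    alpha: float = 0.05
    forest_spec: ForestSpec = field(default_factory=ForestSpec)
    g_spec: ResidualModelSpec = field(default_factory=ResidualModelSpec)
    n_perm: int = 1
    master_seed: int = 0
    companion_vimps: bool = True

    def __post_init__(self) -> None:
        if self.m < 20:
            raise ValueError("m must be >= 20 for quantile estimation")
        if self.m < 100:
            warnings.warn(
                f"m={self.m} subsamples give coarse quantile estimates; "
                "m >= 100 is recommended",
                stacklevel=2,
            )
        if not 0.0 < self.subsample_fraction < 1.0:
            raise ValueError("subsample_fraction must be in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.alpha * self.m < 1:
            warnings.warn(
                f"alpha*m = {self.alpha * self.m:.2f} < 1: the rejection "
                "boundary sits in the tail interpolation region",
                stacklevel=2,
            )


@dataclass
class RvimpResult:
    """Everything the test computed, decisions included."""

    vimp_a: float
    vimp_b_full: float
    density_raw: np.ndarray
    density_shifted: np.ndarray
    q_upper: float
    q_lower: float
    reject_h1: bool
    reject_h2: bool
    p1: float
    p2: float
    alpha: float
    n: int
    z_column: str
    vimps_a: VimpVector | None = None
    vimps_b: VimpVector | None = None

    def to_dict(self, include_density: bool = True) -> dict:
        out = {
            "z_column": self.z_column,
            "n": self.n,
            "alpha": self.alpha,
            "vimp_a": self.vimp_a,
            "vimp_b_full": self.vimp_b_full,
            "q_upper": self.q_upper,
            "q_lower": self.q_lower,
            "reject_h1": bool(self.reject_h1),
            "reject_h2": bool(self.reject_h2),
            "p1": self.p1,
            "p2": self.p2,
        }
        if include_density:
            out["density_raw"] = [float(v) for v in self.density_raw]
            out["density_shifted"] = [float(v) for v in self.density_shifted]
        if self.vimps_a is not None:
            out["vimps_a"] = self.vimps_a.to_dict()
        if self.vimps_b is not None:
            out["vimps_b"] = self.vimps_b.to_dict()
        return out


def draw_subsample(n: int, fraction: float, seed) -> np.ndarray:
    """Distinct row indices: round(fraction*n) drawn uniformly without
    replacement (ties in the rounding go up)."""
    size = int(np.floor(fraction * n + 0.5))
    if size < 1:
        raise ValueError(f"fraction {fraction} rounds to an empty subsample for n={n}")
    if size > n:
        raise ValueError("subsample larger than the data")
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(n, size=size, replace=False))


def empirical_quantile(values: Sequence[float], q: float) -> float:
    """Order-statistic quantile with linear interpolation."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("empty value vector")
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    return float(np.quantile(values, q, method="linear"))


def _seed_int(seed_seq: np.random.SeedSequence) -> int:
    return int(seed_seq.generate_state(1)[0])


def vimp_model_a(data: TabularDataset, cfg: RvimpConfig) -> tuple[float, VimpVector | None]:
    """VIMP of Z in the original forest on all rows (model A)."""
    root = np.random.SeedSequence(cfg.master_seed)
    sub = root.spawn(3)
    return _model_a(data, cfg, sub[0])


def _model_a(data, cfg, seed_seq):
    forest_seed, vimp_seed = (_seed_int(s) for s in seed_seq.spawn(2))
    forest = train_forest(data, cfg.forest_spec.with_seed(forest_seed))
    if cfg.companion_vimps:
        vv = all_vimps(forest, data, cfg.n_perm, vimp_seed)
        return vv[cfg.z_column], vv
    return (
        permutation_vimp(forest, data, cfg.z_column, cfg.n_perm, vimp_seed),
        None,
    )


def vimp_model_b(
    data: TabularDataset,
    cfg: RvimpConfig,
    rows: np.ndarray | None = None,
) -> float:
    """VIMP of eps_Z in the adjusted forest (model B) on the given rows.

    The residual model g is (re)fitted on exactly those rows; the forest
    is trained on them as well, with Z's column replaced by eps_Z.
    """
    root = np.random.SeedSequence(cfg.master_seed)
    sub = root.spawn(3)
    value, _ = _model_b(data, cfg, sub[1], rows)
    return value


def _model_b(data, cfg, seed_seq, rows=None, companions=False):
    g_seed, forest_seed, vimp_seed = (_seed_int(s) for s in seed_seq.spawn(3))
    block = data if rows is None else data.select_rows(np.asarray(rows))
    X_minus, z = block.drop_column(cfg.z_column)
    g = fit_g(X_minus, z, cfg.g_spec.with_seed(g_seed))
    eps = residuals(g, X_minus, z)
    adjusted = block.replace_column(
        cfg.z_column, eps, new_name=cfg.z_column + RESIDUAL_SUFFIX
    )
    forest = train_forest(adjusted, cfg.forest_spec.with_seed(forest_seed))
    resid_col = cfg.z_column + RESIDUAL_SUFFIX
    if companions:
        vv = all_vimps(forest, adjusted, cfg.n_perm, vimp_seed)
        return vv[resid_col], vv
    return (
        permutation_vimp(forest, adjusted, resid_col, cfg.n_perm, vimp_seed),
        None,
    )


def _decide(
    density_raw: np.ndarray,
    vimp_a: float,
    vimp_b_full: float,
    alpha: float,
) -> dict:
    """Shift correction, quantile decisions and add-one p-values.

    Pure function of the m raw subsample values and the two full-sample
    VIMPs; shared by the test driver and the test-suite.
    """
    density_raw = np.asarray(density_raw, dtype=np.float64)
    m = density_raw.size
    shifted = density_raw + (vimp_b_full - density_raw.mean())
    q_upper = empirical_quantile(shifted, 1.0 - alpha)
    q_lower = empirical_quantile(shifted, alpha)
    return {
        "density_shifted": shifted,
        "q_upper": q_upper,
        "q_lower": q_lower,
        "reject_h1": bool(vimp_a > q_upper),
        "reject_h2": bool(q_lower > 0.0),
        "p1": (1 + int((shifted >= vimp_a).sum())) / (m + 1),
        "p2": (1 + int((shifted <= 0.0).sum())) / (m + 1),
    }


def run_rvimp(data: TabularDataset, cfg: RvimpConfig) -> RvimpResult:
    """Full residual-VIMP analysis of one dataset.

    Computes VIMP_A(Z) and VIMP_B(eps_Z) on all n rows, builds the
    m-vector subsample distribution of VIMP_B(eps_Z), applies the mean
    shift and returns quantile decisions and p-values for both
    hypotheses.  Fully deterministic under ``cfg.master_seed``; every
    subsample iteration owns an independent seed branch, so iteration
    results do not depend on execution order.
    """
    data.column_index(cfg.z_column)
    root = np.random.SeedSequence(cfg.master_seed)
    seq_a, seq_b, seq_iters = root.spawn(3)

    vimp_a, vimps_a = _model_a(data, cfg, seq_a)
    vimp_b_full, vimps_b = _model_b(
        data, cfg, seq_b, rows=None, companions=cfg.companion_vimps
    )

    iter_seeds = seq_iters.spawn(cfg.m)
    density_raw = np.empty(cfg.m)
    for b in range(cfg.m):
        draw_seq, model_seq = iter_seeds[b].spawn(2)
        rows = draw_subsample(data.n, cfg.subsample_fraction, draw_seq)
        density_raw[b], _ = _model_b(data, cfg, model_seq, rows=rows)

    d = _decide(density_raw, vimp_a, vimp_b_full, cfg.alpha)
    return RvimpResult(
        vimp_a=float(vimp_a),
        vimp_b_full=float(vimp_b_full),
        density_raw=density_raw,
        density_shifted=d["density_shifted"],
        q_upper=d["q_upper"],
        q_lower=d["q_lower"],
        reject_h1=d["reject_h1"],
        reject_h2=d["reject_h2"],
        p1=d["p1"],
        p2=d["p2"],
        alpha=cfg.alpha,
        n=data.n,
        z_column=cfg.z_column,
        vimps_a=vimps_a,
        vimps_b=vimps_b,
    )
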
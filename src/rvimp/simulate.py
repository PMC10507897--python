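"""Synthetic study designs with controlled correlation structure.

Design A (regression):

    Y = b1 X1 + ... + b5 X5 + b6 Z + eps1,    eps1 ~ N(0, sigma1^2)
    Z = 0.5 X1 + 0.5 X2 + eps2,               eps2 ~ N(0, sigma2^2)

with X1..X5 standard normal, corr(X1, X2) = c and all other pairwise
correlations zero.  The joint distribution of (X, Z, Y) is Gaussian with
a fully analytic covariance, so the marginal correlation C(Y, Z) and the
semipartial correlation spC(Y, Z | X1..X5) = C(Y, eps2) are closed-form
functions of (b, c, sigma1^2, sigma2^2); :func:`solve_sigmas` inverts
that map to hit requested (C, spC) targets.

Design B (classification) keeps the same feature/Z distribution and
passes the linear predictor *including* the noise term through an
inverse-logit to draw a Bernoulli outcome:

    Y ~ B(1, p),  p = 1 / (1 + exp(-(b1 X1 + ... + b6 Z + eps1)))

:func:`run_rejection_study` replays the residual-VIMP test over many
independently generated datasets and reports empirical rejection rates
for both hypotheses — a type-I error estimate where the null holds and a
power estimate where it does not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .datasets import CLASSIFICATION, REGRESSION, TabularDataset
from .resampling import RvimpConfig, run_rvimp

__all__ = [
    "ScenarioSpec",
    "StudyResult",
    "theoretical_moments",
    "solve_sigmas",
    "generate_design_a",
    "generate_design_b",
    "run_rejection_study",
    "POWER_GRID_TARGETS",
    "DESIGN_B_SIGMAS",
]

#: (C(Y,Z), spC(Y,Z)) grid of the regression power study; the two
#: C = 0.9 rows are infeasible for the canonical coefficients (see
#: docs/methods.md) and are listed for completeness
POWER_GRID_TARGETS = [(0.3, 0.1), (0.3, 0.2), (0.6, 0.2), (0.6, 0.4), (0.9, 0.3), (0.9, 0.6)]

#: noise variances of the classification design, shared with the
#: zero-semipartial regression scenario
DESIGN_B_SIGMAS = (4.04, 0.26)

_Z_LOADINGS = np.array([0.5, 0.5, 0.0, 0.0, 0.0])


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one simulated scenario."""

    design: str = "A"
    b: tuple = (0.5, 0.5, 1.0, 0.0, 0.0, 1.0)
    c: float = 0.3
    sigma1_sq: float = 1.0
    sigma2_sq: float = 1.0
    n: int = 500
    target_C: float | None = None
    target_spC: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.design not in ("A", "B"):
            raise ValueError("design must be 'A' or 'B'")
        if len(self.b) != 6:
            raise ValueError("b must have 6 entries")
        if not -1.0 < self.c < 1.0:
            raise ValueError("|c| must be < 1")
        if self.sigma1_sq < 0 or self.sigma2_sq < 0:
            raise ValueError("noise variances must be >= 0")
        if self.n < 1:
            raise ValueError("n must be positive")

    # -- canonical study scenarios -------------------------------------
    @classmethod
    def regression_null(cls, n: int = 500, seed: int = 0) -> "ScenarioSpec":
        """Regression scenario with spC(Y, Z) = 0: Z has no own effect
        (b6 = 0) and its correlation with Y is entirely borrowed."""
        return cls(
            design="A",
            b=(1.0, 1.0, 1.0, 0.0, 0.0, 0.0),
            c=0.3,
            sigma1_sq=DESIGN_B_SIGMAS[0],
            sigma2_sq=DESIGN_B_SIGMAS[1],
            n=n,
            target_C=0.3,
            target_spC=0.0,
            seed=seed,
        )

    @classmethod
    def regression_power(cls, C: float, spC: float, n: int = 500, seed: int = 0) -> "ScenarioSpec":
        """Regression scenario calibrated to (C(Y,Z), spC(Y,Z)); the
        X1-X2 correlation c is set equal to C."""
        b = (0.5, 0.5, 1.0, 0.0, 0.0, 1.0)
        s1, s2 = solve_sigmas(b, C, C, spC)
        return cls(
            design="A", b=b, c=C, sigma1_sq=s1, sigma2_sq=s2, n=n,
            target_C=C, target_spC=spC, seed=seed,
        )

    @classmethod
    def classification(cls, n: int = 500, seed: int = 0) -> "ScenarioSpec":
        return cls(
            design="B",
            b=(1.0, 1.0, 1.0, 0.0, 0.0, 0.0),
            c=0.3,
            sigma1_sq=DESIGN_B_SIGMAS[0],
            sigma2_sq=DESIGN_B_SIGMAS[1],
            n=n,
            seed=seed,
        )

    def with_seed(self, seed: int) -> "ScenarioSpec":
        return replace(self, seed=int(seed))


def _x_covariance(c: float) -> np.ndarray:
    S = np.eye(5)
    S[0, 1] = S[1, 0] = c
    return S


def _moment_pieces(b: Sequence[float], c: float, s1: float, s2: float):
    b = np.asarray(b, dtype=np.float64)
    bx, b6 = b[:5], b[5]
    S = _x_covariance(c)
    w = _Z_LOADINGS
    var_z = w @ S @ w + s2
    cov_xz = S @ w
    cov_zy = bx @ cov_xz + b6 * var_z
    var_y = bx @ S @ bx + 2 * b6 * (bx @ cov_xz) + b6**2 * var_z + s1
    return var_z, var_y, cov_zy, b6


def theoretical_moments(spec: ScenarioSpec) -> tuple[float, float]:
    """Population C(Y, Z) and spC(Y, Z) = C(Y, eps2) for Design A
    parameters."""
    var_z, var_y, cov_zy, b6 = _moment_pieces(
        spec.b, spec.c, spec.sigma1_sq, spec.sigma2_sq
    )
    if var_z <= 0 or var_y <= 0:
        raise ValueError("non-positive variance implied by the parameters")
    C = cov_zy / np.sqrt(var_y * var_z)
    spC = b6 * np.sqrt(spec.sigma2_sq) / np.sqrt(var_y)
    return float(C), float(spC)


def solve_sigmas(
    b: Sequence[float], c: float, target_C: float, target_spC: float
) -> tuple[float, float]:
    """Noise variances (sigma1^2, sigma2^2) hitting the requested
    correlation and semipartial correlation.

    Uses the closed forms: spC pins Var(Y) as a function of sigma2^2,
    which reduces the problem to a one-dimensional root find in sigma2^2
    for the C(Y, Z) equation.  Raises ``ValueError`` when the targets are
    infeasible for the given coefficients.
    """
    b = np.asarray(b, dtype=np.float64)
    b6 = b[5]
    if not 0.0 < target_spC < target_C < 1.0:
        raise ValueError("targets must satisfy 0 < spC < C < 1")
    if b6 == 0.0:
        raise ValueError("spC target > 0 requires b6 != 0")

    bx = b[:5]
    S = _x_covariance(c)
    w = _Z_LOADINGS
    q0 = bx @ S @ bx + 2 * b6 * (bx @ S @ w) + b6**2 * (w @ S @ w)

    def sigma1_sq(s2: float) -> float:
        return b6**2 * s2 / target_spC**2 - (q0 + b6**2 * s2)

    # sigma1^2 > 0 bounds s2 from below
    s2_min = q0 * target_spC**2 / (b6**2 * (1.0 - target_spC**2))

    def f(s2: float) -> float:
        var_z = w @ S @ w + s2
        var_y = b6**2 * s2 / target_spC**2
        cov_zy = bx @ S @ w + b6 * var_z
        return cov_zy / np.sqrt(var_y * var_z) - target_C

    lo = s2_min * (1 + 1e-12) + 1e-300
    grid = np.geomspace(max(lo, 1e-10), 1e6, 200)
    prev, fprev = grid[0], f(grid[0])
    bracket = None
    for hi in grid[1:]:
        fhi = f(hi)
        if np.sign(fprev) != np.sign(fhi):
            bracket = (prev, hi)
            break
        prev, fprev = hi, fhi
    if bracket is None:
        raise ValueError(
            f"targets C={target_C}, spC={target_spC} are infeasible for b={tuple(b)}, c={c}"
        )
    s2 = brentq(f, bracket[0], bracket[1], xtol=1e-14, rtol=1e-15)
    s1 = sigma1_sq(s2)
    if s1 <= 0:
        raise ValueError(
            f"targets C={target_C}, spC={target_spC} imply non-positive sigma1^2"
        )
    return float(s1), float(s2)


def _draw_features(spec: ScenarioSpec, rng: np.random.Generator):
    L = np.linalg.cholesky(_x_covariance(spec.c))
    X = rng.standard_normal((spec.n, 5)) @ L.T
    eps2 = rng.standard_normal(spec.n) * np.sqrt(spec.sigma2_sq)
    Z = X @ _Z_LOADINGS + eps2
    eps1 = rng.standard_normal(spec.n) * np.sqrt(spec.sigma1_sq)
    b = np.asarray(spec.b)
    linpred = X @ b[:5] + b[5] * Z + eps1
    return X, Z, linpred


def _frame(X: np.ndarray, Z: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame(X, columns=[f"X{j}" for j in range(1, 6)])
    df["Z"] = Z
    return df


def generate_design_a(spec: ScenarioSpec) -> TabularDataset:
    """n i.i.d. rows of the Gaussian regression design."""
    rng = np.random.default_rng(spec.seed)
    X, Z, Y = _draw_features(spec, rng)
    return TabularDataset(_frame(X, Z), Y, REGRESSION)


def generate_design_b(spec: ScenarioSpec) -> TabularDataset:
    """n i.i.d. rows of the logistic-link classification design; the
    noise eps1 sits inside the inverse-logit."""
    rng = np.random.default_rng(spec.seed)
    X, Z, linpred = _draw_features(spec, rng)
    prob = 1.0 / (1.0 + np.exp(-linpred))
    Y = (rng.random(spec.n) < prob).astype(np.float64)
    return TabularDataset(_frame(X, Z), Y, CLASSIFICATION)


def generate(spec: ScenarioSpec) -> TabularDataset:
    return generate_design_a(spec) if spec.design == "A" else generate_design_b(spec)


@dataclass
class StudyResult:
    """Empirical rejection rates with Monte-Carlo standard errors."""

    table: pd.DataFrame
    decisions: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _rep_entry(scenario_name, rep, result):
    return {
        "scenario": scenario_name,
        "rep": int(rep),
        "reject_h1": bool(result.reject_h1),
        "reject_h2": bool(result.reject_h2),
    }


def run_rejection_study(
    scenarios: dict[str, ScenarioSpec],
    reps: int,
    cfg: RvimpConfig,
    tested_feature: str = "Z",
    seed: int = 0,
    checkpoint: str | Path | None = None,
) -> StudyResult:
    """Empirical rejection rates of both hypotheses over ``reps``
    replications per scenario.

    Every (scenario, replication) owns an independent seed branch derived
    from ``seed`` and its grid position, so results are invariant to
    execution order and chunking.  With ``checkpoint`` set, per-
    replication decisions are appended to a JSON-lines file and finished
    replications are skipped on re-runs.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    done: dict[tuple, dict] = {}
    ckpt_file = None
    if checkpoint is not None:
        path = Path(checkpoint)
        if path.exists():
            for line in path.read_text().splitlines():
                if line.strip():
                    rec = json.loads(line)
                    done[(rec["scenario"], rec["rep"])] = rec
        ckpt_file = open(path, "a")

    try:
        records = []
        for s_idx, (name, scen) in enumerate(scenarios.items()):
            for rep in range(reps):
                key = (name, rep)
                if key in done:
                    records.append(done[key])
                    continue
                branch = np.random.SeedSequence(seed, spawn_key=(s_idx, rep))
                data_seed, test_seed = branch.generate_state(2) & 0x7FFFFFFF
                data = generate(scen.with_seed(int(data_seed)))
                run_cfg = replace(
                    cfg,
                    z_column=tested_feature,
                    master_seed=int(test_seed),
                    companion_vimps=False,
                )
                result = run_rvimp(data, run_cfg)
                rec = _rep_entry(name, rep, result)
                records.append(rec)
                if ckpt_file is not None:
                    ckpt_file.write(json.dumps(rec) + "\n")
                    ckpt_file.flush()
    finally:
        if ckpt_file is not None:
            ckpt_file.close()

    decisions = pd.DataFrame.from_records(records)
    rows = []
    for name, scen in scenarios.items():
        sub = decisions[decisions["scenario"] == name]
        r = len(sub)
        rate1 = sub["reject_h1"].mean()
        rate2 = sub["reject_h2"].mean()
        rows.append(
            {
                "scenario": name,
                "design": scen.design,
                "n": scen.n,
                "reps": r,
                "rate_h1": rate1,
                "rate_h2": rate2,
                "se_h1": float(np.sqrt(rate1 * (1 - rate1) / r)),
                "se_h2": float(np.sqrt(rate2 * (1 - rate2) / r)),
            }
        )
    return StudyResult(pd.DataFrame(rows), decisions)
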
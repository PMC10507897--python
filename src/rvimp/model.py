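"""Model/Results interface for the residual-VIMP analysis.

``ResidualVimp`` is constructed from data plus the designated feature of
interest; ``fit()`` runs the full analysis (both forests, the residual
model, the subsample distribution and the hypothesis decisions) and
returns a ``ResidualVimpResults`` with a ``summary()`` table and the
plotting helpers.
"""

from __future__ import annotations

import pandas as pd

from .datasets import REGRESSION, TabularDataset, from_dataframe
from .forest import ForestSpec
from .resampling import RvimpConfig, RvimpResult, run_rvimp
from .residualize import ResidualModelSpec

__all__ = ["ResidualVimp", "ResidualVimpResults"]


class ResidualVimp:
    """Residual permutation-importance model for one feature of interest.

    Parameters
    ----------
    data : TabularDataset
        Features (including the column ``z``) and outcome.
    z : str
        Name of the feature of interest.
    forest_spec, g_spec : optional
        Forest hyperparameters and residual-model class (OLS by default).
    """

    def __init__(
        self,
        data: TabularDataset,
        z: str,
        forest_spec: ForestSpec | None = None,
        g_spec: ResidualModelSpec | None = None,
    ):
        data.column_index(z)
        self.data = data
        self.z = z
        self.forest_spec = forest_spec or ForestSpec()
        self.g_spec = g_spec or ResidualModelSpec()

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        outcome: str,
        z: str,
        task: str = REGRESSION,
        **kwargs,
    ) -> "ResidualVimp":
        return cls(from_dataframe(df, outcome, task), z, **kwargs)

    def fit(
        self,
        m: int = 100,
        alpha: float = 0.05,
        subsample_fraction: float = 0.632,
        n_perm: int = 1,
        seed: int = 0,
        companion_vimps: bool = True,
    ) -> "ResidualVimpResults":
        cfg = RvimpConfig(
            z_column=self.z,
            m=m,
            subsample_fraction=subsample_fraction,
            alpha=alpha,
            forest_spec=self.forest_spec,
            g_spec=self.g_spec,
            n_perm=n_perm,
            master_seed=seed,
            companion_vimps=companion_vimps,
        )
        return ResidualVimpResults(self, cfg, run_rvimp(self.data, cfg))


class ResidualVimpResults:
    """Fitted residual-VIMP analysis; wraps the raw result record."""

    def __init__(self, model: ResidualVimp, config: RvimpConfig, result: RvimpResult):
        self.model = model
        self.config = config
        self._result = result

    # transparent access to the result fields (vimp_a, p1, ...)
    def __getattr__(self, name):
        try:
            return getattr(self.__dict__["_result"], name)
        except AttributeError:
            raise AttributeError(name) from None

    @property
    def result(self) -> RvimpResult:
        return self._result

    def companion_table(self) -> pd.DataFrame | None:
        """VIMP of every feature under models A and B, sorted by model A."""
        r = self._result
        if r.vimps_a is None or r.vimps_b is None:
            return None
        a = pd.Series(r.vimps_a.to_dict(), name="vimp_model_a")
        b_raw = r.vimps_b.to_dict()
        # map the residual column back to the original feature name
        b = pd.Series(
            {
                (r.z_column if k.startswith(r.z_column) else k): v
                for k, v in b_raw.items()
            },
            name="vimp_model_b",
        )
        df = pd.concat([a, b], axis=1).sort_values("vimp_model_a", ascending=False)
        df.index.name = "feature"
        return df

    def summary(self) -> str:
        r = self._result
        lines = [
            "Residual permutation importance test",
            "=" * 52,
            f"feature of interest      {r.z_column}",
            f"observations             {r.n}",
            f"subsamples (m)           {len(r.density_raw)}",
            f"alpha                    {r.alpha:g}",
            "-" * 52,
            f"VIMP_A(Z)   marginal     {r.vimp_a: .6g}",
            f"VIMP_B(eps) residual     {r.vimp_b_full: .6g}",
            f"(1-alpha)-quantile       {r.q_upper: .6g}",
            f"alpha-quantile           {r.q_lower: .6g}",
            "-" * 52,
            f"H0(1) importance not borrowed : "
            f"{'rejected' if r.reject_h1 else 'not rejected'} (p = {r.p1:.4g})",
            f"H0(2) residual unimportant    : "
            f"{'rejected' if r.reject_h2 else 'not rejected'} (p = {r.p2:.4g})",
        ]
        comp = self.companion_table()
        if comp is not None:
            lines += ["-" * 52, "per-feature VIMPs (model A / model B):"]
            for name, row in comp.iterrows():
                lines.append(
                    f"  {name:<12s} {row['vimp_model_a']: .6g}   {row['vimp_model_b']: .6g}"
                )
        return "\n".join(lines)

    def plot_density(self, path=None, ax=None):
        from .plots import plot_test_density

        return plot_test_density(self._result, path, ax=ax)

    def plot_comparison(self, top_k: int = 10, path=None, ax=None):
        from .plots import plot_vimp_comparison

        return plot_vimp_comparison(self._result, top_k, path, ax=ax)
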
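"""One-way ANOVA with Dunnett many-to-one comparisons against a control.

Test statistics use the classical homogeneous-variance construction:
pooled within-group variance with ``df = N - n_groups`` residual degrees
of freedom, and two-sided comparisons of every treatment mean against
the control mean.

Adjusted p-values come from the many-to-one multivariate-t reference
distribution.  With group sizes ``n_i`` and control size ``n_0`` the
comparison statistics are equicorrelated in the balanced case
(``rho = 0.5``) and generally correlated as
``rho_ij = lambda_i * lambda_j`` with ``lambda_i = sqrt(n_i/(n_i+n_0))``.
The distribution of ``max_j |T_j|`` is evaluated by Monte-Carlo
integration with a fixed seed and at least 1e5 draws; draws are cached
per (group-size layout, df) so repeated calls — e.g. in simulation
studies — do not resample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["DunnettComparison", "DunnettResult", "anova_dunnett", "significance_stars"]

DEFAULT_MC_DRAWS = 100_000
DEFAULT_MC_SEED = 20240 + 490  # fixed, logged: Monte-Carlo reference seed


@dataclass(frozen=True)
class DunnettComparison:
    condition: str
    mean_diff: float
    t_stat: float
    p_unadjusted: float
    p_adj: float
    stars: str


@dataclass(frozen=True)
class DunnettResult:
    control: str
    comparisons: list[DunnettComparison]
    alpha: float
    k: int
    df: int
    f_stat: float
    f_pvalue: float


def significance_stars(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


_reference_cache: dict[tuple, np.ndarray] = {}


def _max_abs_t_draws(
    n_control: int,
    n_treatments: tuple[int, ...],
    df: int,
    n_draws: int,
    seed: int,
) -> np.ndarray:
    """Sorted Monte-Carlo sample of max_j |T_j| under the complete null."""
    key = (n_control, n_treatments, df, n_draws, seed)
    sample = _reference_cache.get(key)
    if sample is None:
        rng = np.random.default_rng(seed)
        lam = np.sqrt(np.array(n_treatments) / (np.array(n_treatments) + n_control))
        z0 = rng.standard_normal(n_draws)
        z = lam * z0[:, None] + np.sqrt(1.0 - lam**2) * rng.standard_normal(
            (n_draws, len(n_treatments))
        )
        w = np.sqrt(rng.chisquare(df, n_draws) / df)
        sample = np.sort(np.max(np.abs(z / w[:, None]), axis=1))
        _reference_cache[key] = sample
    return sample


def anova_dunnett(
    groups: dict[str, "np.typing.ArrayLike"],
    control: str,
    alpha: float = 0.05,
    n_draws: int = DEFAULT_MC_DRAWS,
    seed: int = DEFAULT_MC_SEED,
) -> DunnettResult:
    """Compare every treatment group against the control group.

    ``groups`` maps condition labels to replicate values and must
    contain the control plus at least one treatment, each with at least
    two replicates.  Raises on zero pooled variance.
    """
    if control not in groups:
        raise ValueError(f"control group {control!r} not present")
    if len(groups) < 2:
        raise ValueError("need the control plus at least one treatment group")
    data = {name: np.asarray(values, dtype=float) for name, values in groups.items()}
    for name, values in data.items():
        if values.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 replicates")

    treatments = [name for name in data if name != control]
    x0 = data[control]
    n_total = sum(v.size for v in data.values())
    n_groups = len(data)
    df = n_total - n_groups

    sse = sum(float(((v - v.mean()) ** 2).sum()) for v in data.values())
    if sse == 0.0:
        raise ValueError("zero pooled variance: all groups are constant")
    mse = sse / df

    grand = np.concatenate(list(data.values())).mean()
    ssb = sum(v.size * (v.mean() - grand) ** 2 for v in data.values())
    f_stat = (ssb / (n_groups - 1)) / mse
    f_pvalue = float(sps.f.sf(f_stat, n_groups - 1, df))

    ns = tuple(data[name].size for name in treatments)
    reference = _max_abs_t_draws(x0.size, ns, df, n_draws, seed)

    comparisons = []
    for name in treatments:
        x = data[name]
        diff = float(x.mean() - x0.mean())
        se = np.sqrt(mse * (1.0 / x.size + 1.0 / x0.size))
        t = diff / se
        p_unadj = float(2.0 * sps.t.sf(abs(t), df))
        # P(max_j |T_j| >= |t|) from the sorted Monte-Carlo reference
        idx = np.searchsorted(reference, abs(t), side="left")
        p_adj = float((reference.size - idx) / reference.size)
        comparisons.append(
            DunnettComparison(
                condition=name,
                mean_diff=diff,
                t_stat=float(t),
                p_unadjusted=p_unadj,
                p_adj=p_adj,
                stars=significance_stars(p_adj),
            )
        )
    return DunnettResult(
        control=control,
        comparisons=comparisons,
        alpha=alpha,
        k=len(treatments),
        df=df,
        f_stat=float(f_stat),
        f_pvalue=f_pvalue,
    )
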
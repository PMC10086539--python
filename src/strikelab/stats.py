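"""Statistical comparison of strike variables between setups.

For each strike variable the design is a two-factor mixed model: setup
(open vs walled, fixed), individual (random), and their interaction
(random), with repeated trials per individual-by-setup cell. For balanced
data the classical expected-mean-squares F-tests apply:

    F_setup       = MS_setup / MS_interaction        df (a-1, (a-1)(b-1))
    F_individual  = MS_individual / MS_interaction   df (b-1, (a-1)(b-1))
    F_interaction = MS_interaction / MS_error        df ((a-1)(b-1), N-ab)

(the unrestricted mixed-model convention, which REML fitters also follow
for balanced designs). Mildly unbalanced designs are handled by the
unweighted-means approximation: cell means with the harmonic-mean cell
size.

Variance homogeneity across setups is assessed with the Brown-Forsythe
modification of Levene's test (one-way ANOVA on absolute deviations from
group medians), and families of per-variable p-values are corrected with
the Holm step-down procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MixedAnovaResult",
    "mixed_anova",
    "brown_forsythe",
    "holm_adjust",
    "stats_table",
]


@dataclass(frozen=True)
class EffectTest:
    F: float
    p: float
    df_num: float
    df_den: float
    ms_num: float
    ms_den: float


@dataclass(frozen=True)
class MixedAnovaResult:
    setup: EffectTest
    individual: EffectTest
    interaction: EffectTest
    balanced: bool
    n_cells: int


def _ftest(ss_num, df_num, ss_den, df_den) -> EffectTest:
    ms_num = ss_num / df_num
    ms_den = ss_den / df_den
    if ms_den <= 0:
        F = np.inf if ms_num > 0 else 0.0
    else:
        F = ms_num / ms_den
    p = float(scipy.stats.f.sf(F, df_num, df_den))
    return EffectTest(float(F), p, float(df_num), float(df_den), float(ms_num), float(ms_den))


def mixed_anova(
    table: pd.DataFrame,
    value: str = "value",
    setup: str = "setup",
    individual: str = "individual",
) -> MixedAnovaResult:
    """Two-factor mixed-model ANOVA of one strike variable.

    ``table`` must hold one row per trial with columns for the individual,
    the setup, and the variable's value; both setups and at least two
    individuals must be present, and every individual-by-setup cell needs at
    least two trials.
    """
    df = table[[individual, setup, value]].dropna()
    setups = sorted(df[setup].unique())
    indivs = sorted(df[individual].unique())
    a, b = len(setups), len(indivs)
    if a < 2:
        raise ValueError("both setups must be present")
    if b < 2:
        raise ValueError("need at least 2 individuals")

    counts = df.groupby([setup, individual], observed=True)[value].count()
    for s in setups:
        for i in indivs:
            n = counts.get((s, i), 0)
            if n < 2:
                raise ValueError(
                    f"cell (setup={s!r}, individual={i!r}) has {n} trial(s); "
                    f"need at least 2"
                )
    balanced = counts.nunique() == 1
    cell_means = df.groupby([setup, individual], observed=True)[value].mean().unstack()
    cell_means = cell_means.loc[setups, indivs].to_numpy()  # (a, b)
    # effective per-cell n: exact when balanced, harmonic mean otherwise
    n_eff = float(scipy.stats.hmean(counts.to_numpy()))

    mean_s = cell_means.mean(axis=1)  # per-setup means of cell means
    mean_i = cell_means.mean(axis=0)
    grand = cell_means.mean()

    ss_setup = n_eff * b * np.sum((mean_s - grand) ** 2)
    ss_indiv = n_eff * a * np.sum((mean_i - grand) ** 2)
    ss_inter = n_eff * np.sum(
        (cell_means - mean_s[:, None] - mean_i[None, :] + grand) ** 2
    )
    within = df.set_index([setup, individual])[value]
    ss_err = 0.0
    for (s, i), grp in within.groupby(level=[0, 1], observed=True):
        ss_err += float(np.sum((grp.to_numpy() - grp.mean()) ** 2))

    N = len(df)
    df_setup, df_indiv = a - 1, b - 1
    df_inter = (a - 1) * (b - 1)
    df_err = N - a * b

    return MixedAnovaResult(
        setup=_ftest(ss_setup, df_setup, ss_inter, df_inter),
        individual=_ftest(ss_indiv, df_indiv, ss_inter, df_inter),
        interaction=_ftest(ss_inter, df_inter, ss_err, df_err),
        balanced=bool(balanced),
        n_cells=a * b,
    )


def brown_forsythe(*groups) -> tuple[float, float]:
    """Brown-Forsythe (median-centered Levene) test of equal spread.

    Accepts two or more groups of observations; each needs at least two.
    Returns (F, p).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for k, g in enumerate(groups):
        if len(g) < 2:
            raise ValueError(f"group {k} has fewer than 2 observations")
    stat, p = scipy.stats.levene(*groups, center="median")
    return float(stat), float(p)


def holm_adjust(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Holm step-down multiplicity correction.

    Returns (reject flags, adjusted p-values) in the input order. The
    procedure sorts the m raw p-values ascending and rejects while
    p_(i) <= alpha / (m - i + 1), stopping at the first failure; adjusted
    p-values are the running maximum of (m - i + 1) * p_(i), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be finite and in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return reject, p_adj


def stats_table(
    metrics: pd.DataFrame,
    variables: list[str],
    alpha: float = 0.05,
    setup: str = "setup",
    individual: str = "individual",
) -> pd.DataFrame:
    """Per-variable mixed ANOVA + Brown-Forsythe, Holm-corrected by family.

    For each variable the table reports the three mixed-model effect tests
    and two Brown-Forsythe readings: "pooled" compares the two setups with
    individuals pooled, "cells" compares all individual-by-setup cells.
    Holm correction is applied separately to each family of per-variable
    p-values (setup, individual, interaction, both Brown-Forsythe variants).
    """
    rows = []
    for var in variables:
        res = mixed_anova(metrics, value=var, setup=setup, individual=individual)
        by_setup = [g[var].to_numpy() for _, g in metrics.groupby(setup, observed=True)]
        bf_pool_F, bf_pool_p = brown_forsythe(*by_setup)
        cells = [
            g[var].to_numpy()
            for _, g in metrics.groupby([setup, individual], observed=True)
        ]
        bf_cell_F, bf_cell_p = brown_forsythe(*cells)
        rows.append(
            {
                "variable": var,
                "setup_F": res.setup.F,
                "setup_p": res.setup.p,
                "individual_F": res.individual.F,
                "individual_p": res.individual.p,
                "interaction_F": res.interaction.F,
                "interaction_p": res.interaction.p,
                "bf_pooled_F": bf_pool_F,
                "bf_pooled_p": bf_pool_p,
                "bf_cells_F": bf_cell_F,
                "bf_cells_p": bf_cell_p,
                "balanced": res.balanced,
            }
        )
    out = pd.DataFrame(rows)
    for fam in ("setup_p", "individual_p", "interaction_p", "bf_pooled_p", "bf_cells_p"):
        reject, adj = holm_adjust(out[fam].to_numpy(), alpha=alpha)
        out[fam.replace("_p", "_p_holm")] = adj
        out[fam.replace("_p", "_significant")] = reject
    return out
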
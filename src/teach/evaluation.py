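"""Retrieval scoring (d-prime) and the statistical analysis pipeline.

Retrieval fidelity on one test trial is scored with signal detection:
d' = Z(hit rate) - Z(false-alarm rate), where the hit rate is the
proportion of the target's active units that are active in the
retrieved output-pool pattern, and the false-alarm rate the proportion
of the target's inactive units that are active.  Rates are clipped to
[1/(2N), 1 - 1/(2N)] (N the respective unit count) so perfect or empty
retrievals stay finite.

Across runs, the analysis mirrors the experimental one: per-run mean
d' difference between nontargets and list-matched controls per design
cell, planned paired comparisons (t, Cohen's d) per cell, and a mixed
2 (temporal) x 2 (semantic) x 2 (sleep) ANOVA with sleep as a
between-run factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import PoolPattern

__all__ = [
    "ScoreResult",
    "dprime",
    "aggregate",
    "planned_comparison",
    "three_way_anova",
    "condition_stats",
    "CELL_COLUMNS",
]

CELL_COLUMNS = ["temporal", "semantic", "sleep_state"]


@dataclass(frozen=True)
class ScoreResult:
    hit_rate: float
    fa_rate: float
    dprime: float


def dprime(
    target: PoolPattern,
    output_activity: np.ndarray,
    active_threshold: float = 0.5,
) -> ScoreResult:
    """Score a retrieved activity vector against a binary target pattern."""
    out = np.asarray(output_activity, dtype=float)
    tgt = target.units.astype(bool)
    if out.shape != tgt.shape:
        raise ValueError("target and output must have the same length")
    n_sig = int(tgt.sum())
    n_noise = int((~tgt).sum())
    if n_sig == 0 or n_noise == 0:
        raise ValueError("target must have both active and inactive units")
    active = out > active_threshold
    hit = float(np.sum(active & tgt) / n_sig)
    fa = float(np.sum(active & ~tgt) / n_noise)
    hit_c = float(np.clip(hit, 1 / (2 * n_sig), 1 - 1 / (2 * n_sig)))
    fa_c = float(np.clip(fa, 1 / (2 * n_noise), 1 - 1 / (2 * n_noise)))
    d = float(stats.norm.ppf(hit_c) - stats.norm.ppf(fa_c))
    return ScoreResult(hit_rate=hit_c, fa_rate=fa_c, dprime=d)


def aggregate(results: pd.DataFrame) -> pd.DataFrame:
    """Per-(run, cell) nontarget/control means and their difference.

    Expects tidy trial rows with columns ``run``, the cell columns,
    ``role``, ``matched_control`` and ``dprime``.  The control mean uses
    only list-position-matched control pairmates (all controls in the
    close condition, the earlier-list pairmate in the far condition),
    removing the serial-position confound.
    """
    required = {"run", "role", "matched_control", "dprime", *CELL_COLUMNS}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    rows = []
    group_cols = ["run", *CELL_COLUMNS] + (
        ["variant"] if "variant" in results.columns else []
    )
    for key, grp in results.groupby(group_cols, sort=True):
        nt = grp.loc[grp.role == "nontarget", "dprime"]
        ctl = grp.loc[
            (grp.role == "control") & grp.matched_control, "dprime"
        ]
        if nt.empty or ctl.empty:
            raise ValueError(f"cell {key} lacks nontarget or control trials")
        rec = dict(zip(group_cols, key))
        rec.update(
            nontarget=float(nt.mean()),
            control=float(ctl.mean()),
            diff=float(nt.mean() - ctl.mean()),
        )
        rows.append(rec)
    return pd.DataFrame(rows)


def planned_comparison(x, y=None):
    """Paired comparison across runs: t, df, p and Cohen's d.

    With one argument, tests the per-run differences against zero; with
    two, tests paired x vs y.  Cohen's d is mean(diff)/sd(diff).
    """
    x = np.asarray(x, dtype=float)
    diffs = x if y is None else x - np.asarray(y, dtype=float)
    n = diffs.size
    if n < 2:
        raise ValueError("need at least two paired observations")
    sd = diffs.std(ddof=1)
    if sd == 0:
        if np.allclose(diffs, 0):
            return {"t": 0.0, "df": n - 1, "p": 1.0, "cohens_d": 0.0}
        raise ValueError("zero variance with nonzero mean: d undefined")
    mean = diffs.mean()
    t = mean / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), n - 1)
    return {
        "t": float(t),
        "df": n - 1,
        "p": float(p),
        "cohens_d": float(mean / sd),
    }


def three_way_anova(diffs: pd.DataFrame) -> pd.DataFrame:
    """Mixed 2x2x2 ANOVA on per-run diff scores.

    ``sleep_state`` is treated as a between-run factor (two independent
    groups of n runs), ``temporal`` and ``semantic`` as within-run
    factors, mirroring the split-plot design with its F(1, 2n-2) within
    error terms.  Returns the full effect table; the row named
    ``temporal:semantic:sleep_state`` is the three-way interaction.
    """
    needed = {"run", "diff", *CELL_COLUMNS}
    if not needed <= set(diffs.columns):
        raise ValueError(f"diffs table needs columns {sorted(needed)}")
    wide = diffs.pivot_table(
        index=["sleep_state", "run"],
        columns=["temporal", "semantic"],
        values="diff",
    )
    if wide.isna().any().any() or wide.shape[1] != 4:
        raise ValueError("unbalanced design: every run needs all 4 cells")
    groups = wide.index.get_level_values(0).unique()
    if len(groups) != 2:
        raise ValueError("need both wake and sleep groups")
    n = wide.loc[groups[0]].shape[0]
    if wide.loc[groups[1]].shape[0] != n:
        raise ValueError("groups must have equal run counts")

    # Y[g, s, a, b]: group (sleep), subject (run), temporal, semantic.
    Y = np.stack(
        [
            wide.loc[g].to_numpy().reshape(n, 2, 2)
            for g in sorted(groups)
        ]
    )
    M = Y.mean()
    subj = Y.mean(axis=(2, 3))          # (2, n)
    g_m = Y.mean(axis=(1, 2, 3))        # (2,)
    a_m = Y.mean(axis=(0, 1, 3))        # (2,)
    b_m = Y.mean(axis=(0, 1, 2))        # (2,)
    ga_m = Y.mean(axis=(1, 3))          # (2, 2)
    gb_m = Y.mean(axis=(1, 2))          # (2, 2)
    ab_m = Y.mean(axis=(0, 1))          # (2, 2)
    gab_m = Y.mean(axis=1)              # (2, 2, 2)
    Ya = Y.mean(axis=3)                 # (2, n, 2)
    Yb = Y.mean(axis=2)                 # (2, n, 2)

    ss_total = np.sum((Y - M) ** 2)
    ss_g = 4 * n * np.sum((g_m - M) ** 2)
    ss_s_g = 4 * np.sum((subj - g_m[:, None]) ** 2)
    ss_a = 4 * n * np.sum((a_m - M) ** 2)
    ss_ga = 2 * n * np.sum(
        (ga_m - g_m[:, None] - a_m[None, :] + M) ** 2
    )
    ss_as_g = 2 * np.sum(
        (
            Ya
            - subj[:, :, None]
            - ga_m[:, None, :]
            + g_m[:, None, None]
        )
        ** 2
    )
    ss_b = 4 * n * np.sum((b_m - M) ** 2)
    ss_gb = 2 * n * np.sum(
        (gb_m - g_m[:, None] - b_m[None, :] + M) ** 2
    )
    ss_bs_g = 2 * np.sum(
        (
            Yb
            - subj[:, :, None]
            - gb_m[:, None, :]
            + g_m[:, None, None]
        )
        ** 2
    )
    ss_ab = 2 * n * np.sum(
        (ab_m - a_m[:, None] - b_m[None, :] + M) ** 2
    )
    ss_gab = n * np.sum(
        (
            gab_m
            - ga_m[:, :, None]
            - gb_m[:, None, :]
            - ab_m[None, :, :]
            + g_m[:, None, None]
            + a_m[None, :, None]
            + b_m[None, None, :]
            - M
        )
        ** 2
    )
    ss_abs_g = ss_total - (
        ss_g + ss_s_g + ss_a + ss_ga + ss_as_g + ss_b + ss_gb + ss_bs_g
        + ss_ab + ss_gab
    )

    df_err_between = 2 * n - 2
    df_err_within = 2 * n - 2
    rows = []

    def effect(name, ss, ss_err, df_err):
        if ss_err > 0:
            F = (ss / 1) / (ss_err / df_err)
        else:
            # no residual variation: a zero effect is F = 0, anything
            # else is unboundedly large
            F = 0.0 if np.isclose(ss, 0.0) else np.inf
        rows.append(
            {
                "effect": name,
                "ss": float(ss),
                "df1": 1,
                "df2": df_err,
                "F": float(F),
                "p": float(stats.f.sf(F, 1, df_err)),
                "eta_p_sq": float(ss / (ss + ss_err)) if ss + ss_err else 0.0,
            }
        )

    effect("sleep_state", ss_g, ss_s_g, df_err_between)
    effect("temporal", ss_a, ss_as_g, df_err_within)
    effect("temporal:sleep_state", ss_ga, ss_as_g, df_err_within)
    effect("semantic", ss_b, ss_bs_g, df_err_within)
    effect("semantic:sleep_state", ss_gb, ss_bs_g, df_err_within)
    effect("temporal:semantic", ss_ab, ss_abs_g, df_err_within)
    effect("temporal:semantic:sleep_state", ss_gab, ss_abs_g, df_err_within)
    return pd.DataFrame(rows)


def condition_stats(diffs: pd.DataFrame) -> dict:
    """Per-cell planned comparisons plus the three-way interaction.

    Returns a JSON-serialisable dict: one entry per design cell with the
    mean diff, its 95% CI and the paired-comparison statistics, plus the
    mixed-ANOVA table.
    """
    cells = {}
    for key, grp in diffs.groupby(CELL_COLUMNS, sort=True):
        d = grp.sort_values("run")["diff"].to_numpy()
        n = d.size
        mean = float(d.mean())
        sem = float(d.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        half = float(stats.t.ppf(0.975, n - 1) * sem) if n > 1 else 0.0
        entry = {
            "mean_diff": mean,
            "ci95": [mean - half, mean + half],
            "n_runs": n,
        }
        if n > 1:
            entry.update(planned_comparison(d))
        cells["/".join(key)] = entry
    out = {"cells": cells}
    try:
        table = three_way_anova(diffs)
        out["anova"] = table.to_dict(orient="records")
        inter = table.loc[
            table.effect == "temporal:semantic:sleep_state"
        ].iloc[0]
        out["three_way_interaction"] = {
            "F": float(inter.F),
            "df": [int(inter.df1), int(inter.df2)],
            "p": float(inter.p),
            "eta_p_sq": float(inter.eta_p_sq),
        }
    except ValueError:
        pass  # subset of cells: planned comparisons only
    return out
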
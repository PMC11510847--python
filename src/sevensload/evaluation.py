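"""Supervised evaluation: actual vs. model-predicted sRPE across games.

Tournaments run five or six games over consecutive days, and load is known
to drift across them. This module compares observed session RPE with the
workload model's predictions across game numbers: a two-factor ANOVA
(game number x sRPE type) with the athlete as a blocking factor removed
into an error stratum, a Tukey HSD post hoc on the game-number marginal
means, and Holm-adjusted paired comparisons of the two sRPE types within
each game. Significance is reported at alpha = 0.01 throughout.

The athlete blocking stratum is a conventional choice; published
repeated-measures layouts for data like these are rarely reconstructible
exactly, so conclusions should rest on the significance pattern rather than
specific F values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDesignError, PairingError
from .features import StudyDataset
from .model import WorkloadModelFit, predict_srpe

LONG_COLUMNS = ["athlete_id", "match_id", "game_number", "srpe_type", "srpe_au"]
SRPE_TYPES = ("actual", "predicted")


@dataclass
class AnovaTable:
    """Per-term df, sums of squares, F and p; degenerate terms noted."""

    table: pd.DataFrame  # index: game_number, srpe_type, interaction, athlete, residual
    notes: list[str] = field(default_factory=list)

    def f(self, term: str) -> float:
        return float(self.table.loc[term, "F"])

    def p(self, term: str) -> float:
        return float(self.table.loc[term, "p"])


@dataclass
class PosthocResult:
    """Pairwise comparisons with multiplicity-adjusted p values."""

    comparisons: pd.DataFrame  # columns: pair, mean_diff, p_adj, significant
    alpha: float
    method: str

    def significant_pairs(self) -> list[tuple]:
        return [
            tuple(row["pair"])
            for _, row in self.comparisons.iterrows()
            if row["significant"]
        ]


def make_long_table(dataset: StudyDataset, fit: WorkloadModelFit) -> pd.DataFrame:
    """Two rows per complete record: the observed and the predicted sRPE."""
    df = dataset.records if isinstance(dataset, StudyDataset) else dataset
    if df["srpe_au"].isna().any():
        raise ValueError("evaluation requires complete records; run drop_incomplete")
    predicted = predict_srpe(fit, df, include_random=True)
    base = df[["athlete_id", "match_id", "game_number"]]
    actual = base.assign(srpe_type="actual", srpe_au=df["srpe_au"].to_numpy())
    pred = base.assign(srpe_type="predicted", srpe_au=predicted.to_numpy())
    return (
        pd.concat([actual, pred], ignore_index=True)[LONG_COLUMNS]
        .sort_values(["match_id", "athlete_id", "srpe_type"])
        .reset_index(drop=True)
    )


def _validate_long(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in LONG_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"long table missing columns: {missing}")
    games = sorted(table["game_number"].unique())
    if len(games) < 2:
        raise DegenerateDesignError("need at least 2 game numbers")
    counts = table.groupby("game_number")["srpe_au"].count()
    thin = counts[counts < 2]
    if len(thin):
        raise DegenerateDesignError(
            f"game numbers with fewer than 2 observations: {thin.index.tolist()}"
        )
    return table.sort_values(LONG_COLUMNS[:4]).reset_index(drop=True)


def rm_anova(table: pd.DataFrame) -> AnovaTable:
    """Two-factor ANOVA (game number x sRPE type) with an athlete stratum.

    Fitted as an ordinary least-squares model with the athlete as a fixed
    blocking factor, using type-II sums of squares; the athlete stratum
    absorbs between-player variation so the game and type effects are tested
    against within-player residual error. A term whose residual variance is
    exactly zero (e.g. identical values in every cell) is reported with
    F = 0 and a note instead of a division error.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    table = _validate_long(table)
    data = table.copy()
    data["game_number"] = data["game_number"].astype(int)
    model = smf.ols(
        "srpe_au ~ C(game_number) * C(srpe_type) + C(athlete_id)", data=data
    ).fit()
    notes: list[str] = []
    if model.ssr <= 1e-12 * max(1.0, float(np.sum(data["srpe_au"] ** 2))):
        # no residual variation: every F is undefined; report zeros
        notes.append("zero residual variation; F statistics reported as 0")
        terms = ["game_number", "srpe_type", "interaction", "athlete", "residual"]
        out = pd.DataFrame(
            {"df": [0] * 5, "sum_sq": [0.0] * 5, "F": [0.0] * 5, "p": [1.0] * 5},
            index=terms,
        )
        return AnovaTable(table=out, notes=notes)
    aov = anova_lm(model, typ=2)
    rename = {
        "C(game_number)": "game_number",
        "C(srpe_type)": "srpe_type",
        "C(game_number):C(srpe_type)": "interaction",
        "C(athlete_id)": "athlete",
        "Residual": "residual",
    }
    aov = aov.rename(index=rename)
    out = pd.DataFrame(
        {
            "df": aov["df"].astype(int),
            "sum_sq": aov["sum_sq"],
            "F": aov["F"].fillna(0.0),
            "p": aov["PR(>F)"].fillna(1.0),
        }
    )
    order = ["game_number", "srpe_type", "interaction", "athlete", "residual"]
    return AnovaTable(table=out.loc[order], notes=notes)


def tukey_game(table: pd.DataFrame, alpha: float = 0.01) -> PosthocResult:
    """Tukey HSD on the game-number marginal means (all 15 pairs for 6 games)."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    table = _validate_long(table)
    values = table["srpe_au"].to_numpy()
    groups = table["game_number"].astype(int).to_numpy()
    games = np.unique(groups)
    within_var = sum(
        np.var(values[groups == g]) * (groups == g).sum() for g in games
    )
    if within_var <= 1e-12 * max(1.0, float(np.sum(values**2))):
        pairs = [
            (int(a), int(b)) for i, a in enumerate(games) for b in games[i + 1 :]
        ]
        comp = pd.DataFrame(
            {
                "pair": pairs,
                "mean_diff": [
                    float(values[groups == b].mean() - values[groups == a].mean())
                    for a, b in pairs
                ],
                "p_adj": 1.0,
                "significant": False,
            }
        )
        return PosthocResult(comparisons=comp, alpha=alpha, method="tukey-hsd")
    res = pairwise_tukeyhsd(values, groups, alpha=alpha)
    frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    comp = pd.DataFrame(
        {
            "pair": [(int(a), int(b)) for a, b in zip(frame["group1"], frame["group2"])],
            "mean_diff": res.meandiffs,
            "p_adj": res.pvalues,
            "significant": res.reject,
        }
    )
    return PosthocResult(comparisons=comp, alpha=alpha, method="tukey-hsd")


def pairwise_type_by_game(table: pd.DataFrame, alpha: float = 0.01) -> PosthocResult:
    """Paired actual-vs-predicted comparison within each game number.

    Pairs on (athlete, match); rows without a partner raise a
    :class:`PairingError` listing the orphans. p values from paired t tests
    are Holm-adjusted across the games. Identical pairs everywhere in a game
    yield an undefined t, reported as p = 1 (no evidence of a difference).
    """
    table = _validate_long(table)
    wide = table.pivot_table(
        index=["athlete_id", "match_id", "game_number"],
        columns="srpe_type",
        values="srpe_au",
        aggfunc="first",
    )
    orphans = wide[wide[list(SRPE_TYPES)].isna().any(axis=1)]
    if len(orphans):
        raise PairingError(
            f"{len(orphans)} player-matches lack a paired sRPE row",
            orphans=orphans.index.tolist(),
        )
    wide = wide.reset_index().sort_values(["game_number", "match_id", "athlete_id"])
    games = sorted(wide["game_number"].unique())
    raw_p, diffs = [], []
    for g in games:
        sub = wide[wide["game_number"] == g]
        d = sub["actual"].to_numpy() - sub["predicted"].to_numpy()
        diffs.append(float(np.mean(d)))
        if np.allclose(d, d[0]) and np.isclose(np.std(d), 0.0):
            raw_p.append(1.0 if np.isclose(d[0], 0.0) else 0.0)
        else:
            raw_p.append(float(stats.ttest_rel(sub["actual"], sub["predicted"]).pvalue))
    from statsmodels.stats.multitest import multipletests

    reject, p_adj, *_ = multipletests(raw_p, alpha=alpha, method="holm")
    comp = pd.DataFrame(
        {
            "pair": [(int(g), "actual-vs-predicted") for g in games],
            "mean_diff": diffs,
            "p_raw": raw_p,
            "p_adj": p_adj,
            "significant": reject,
        }
    )
    return PosthocResult(comparisons=comp, alpha=alpha, method="paired-t-holm")


def evaluation_summary(
    anova: AnovaTable, tukey: PosthocResult, pairwise: PosthocResult
) -> str:
    """Plain-text narrative of the evaluation, mirroring how such results read."""
    lines = ["Supervised evaluation of predicted vs. actual sRPE", ""]
    for term in ("game_number", "srpe_type", "interaction"):
        row = anova.table.loc[term]
        lines.append(
            f"{term}: F({int(row['df'])}, {int(anova.table.loc['residual', 'df'])})"
            f" = {row['F']:.3f}, p = {row['p']:.4g}"
        )
    sig = tukey.significant_pairs()
    lines.append("")
    lines.append(
        "Tukey HSD on game number (alpha = %.2f): %s"
        % (tukey.alpha, ", ".join(f"{a} vs {b}" for a, b in sig) if sig else "no significant pairs")
    )
    sig_games = [p[0] for p in pairwise.significant_pairs()]
    lines.append(
        "Actual vs predicted within game (Holm): "
        + (f"significant at games {sig_games}" if sig_games else "no significant games")
    )
    for note in anova.notes:
        lines.append(f"note: {note}")
    return "\n".join(lines)
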
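"""Resistance scoring: performance, robustness, rankings, RVA and PI.

Performance compares a strain with the other strains at one condition and
inhibitory level (cross-sectional, weighted sum of oriented min-max-scaled
growth parameters); robustness measures how well a strain maintains its own
growth parameters as the inhibitory level rises (longitudinal retention
against the least inhibitory level).  Per-level performance scores are
integrated across levels into a final per-condition strain ranking with
decile ranking values; robustness is cross-level by construction.

Rank variability analysis (RVA) re-ranks under weight vectors sampled
uniformly on the simplex; parameter-influence (PI) scores measure the rank
change when one parameter is up-weighted, normalized so the extreme entry
over all parameters and conditions is ±1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .growthio import PARAM_FIELDS

__all__ = [
    "WeightVector",
    "TIME_LIKE",
    "orient_and_normalize",
    "performance_level",
    "robustness_strain",
    "integrate_levels",
    "condition_scores",
    "rank_condition",
    "ranking_table",
    "top_frequency",
    "rank_variability",
    "parameter_influence",
    "pi_correlation",
]

#: parameters where smaller is better (inverted before scoring)
TIME_LIKE = frozenset({"lag_h", "t_half"})


@dataclass(frozen=True)
class WeightVector:
    """Nonnegative weights over the five growth parameters, sum-normalized."""

    w: tuple[float, ...]

    def __init__(self, w=None):
        if w is None:
            w = (1.0,) * len(PARAM_FIELDS)
        arr = np.asarray(tuple(w), dtype=float)
        if arr.size != len(PARAM_FIELDS):
            raise ValueError(f"need {len(PARAM_FIELDS)} weights")
        if np.any(arr < 0) or arr.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive sum")
        object.__setattr__(self, "w", tuple(arr / arr.sum()))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.w)


def _level_slice(table: pd.DataFrame, condition: str, level: int) -> pd.DataFrame:
    sel = table[(table["condition"] == condition) & (table["level"] == level)]
    return sel.set_index("strain")


def orient_and_normalize(level_table: pd.DataFrame) -> pd.DataFrame | None:
    """Oriented, min-max scaled strains x 5 matrix in [0, 1] for one level.

    Time-like parameters are negated so larger is better; each parameter is
    min-max scaled across the growing strains; non-growers are pinned to 0.
    Degenerate range among growers: 0.5 when every strain grew, 1.0 when
    non-growers exist (the growers still beat them).  Returns None when no
    strain grew (level unusable).
    """
    if level_table.index.name != "strain":
        level_table = level_table.set_index("strain")
    grew = level_table["grew"].astype(bool)
    if not grew.any():
        return None
    out = pd.DataFrame(0.0, index=level_table.index, columns=list(PARAM_FIELDS))
    any_nongrower = (~grew).any()
    for k in PARAM_FIELDS:
        x = level_table.loc[grew, k].astype(float)
        if k in TIME_LIKE:
            x = -x
        lo, hi = x.min(), x.max()
        if hi > lo:
            out.loc[grew, k] = (x - lo) / (hi - lo)
        else:
            out.loc[grew, k] = 1.0 if any_nongrower else 0.5
    return out


def performance_level(oriented: pd.DataFrame, w: WeightVector) -> pd.Series:
    """Per-strain performance at one level: weighted sum of oriented values."""
    return oriented.loc[:, list(PARAM_FIELDS)] @ w.as_array()


def robustness_strain(
    table: pd.DataFrame, condition: str, w: WeightVector, eps: float = 1e-12
) -> pd.Series:
    """Per-strain robustness for one condition.

    For each parameter, the retention at level l >= 1 is the ratio of the
    value at l to the value at the reference (least inhibitory) level,
    clamped to [0, 1], with time-like parameters inverted (reference/level)
    before the ratio; non-growing levels retain 0.  Robustness is the
    weighted mean over parameters of the mean retention over levels.
    Strains that did not grow at the reference level are NaN (ranked last).
    """
    sub = table[table["condition"] == condition]
    levels = sorted(sub["level"].unique())
    if len(levels) < 2:
        raise ValueError("robustness needs at least 2 observed levels")
    grew = sub.pivot(index="strain", columns="level", values="grew").fillna(False)
    strains = grew.index
    ref_lev, rest = levels[0], levels[1:]
    ok_ref = grew[ref_lev].astype(bool).to_numpy()
    warr = w.as_array()
    retention = np.zeros((len(strains), len(PARAM_FIELDS)))
    for ki, k in enumerate(PARAM_FIELDS):
        vals = sub.pivot(index="strain", columns="level", values=k)
        a = vals[ref_lev].to_numpy(dtype=float)
        acc = np.zeros(len(strains))
        for lev in rest:
            b = (vals[lev].to_numpy(dtype=float) if lev in vals
                 else np.full(len(strains), np.nan))
            ok = grew[lev].astype(bool).to_numpy() & np.isfinite(b)
            if k in TIME_LIKE:
                ratio = a / np.maximum(b, eps)
            else:
                ratio = b / np.maximum(a, eps)
            acc += np.where(ok, np.clip(ratio, 0.0, 1.0), 0.0)
        retention[:, ki] = acc / len(rest)
    score = retention @ warr
    out = pd.Series(np.where(ok_ref, score, np.nan),
                    index=pd.Index(strains, name="strain"))
    return out


def integrate_levels(
    level_scores: dict[int, pd.Series], level_weights: dict[int, float] | None = None
) -> pd.Series:
    """Integrate per-level performance scores into one per-strain score.

    Default: unweighted mean over usable levels; optional level weights.
    """
    usable = {l: s for l, s in level_scores.items() if s is not None}
    if not usable:
        raise ValueError("no usable level")
    frame = pd.DataFrame(usable)
    if level_weights:
        wts = np.array([level_weights.get(l, 1.0) for l in frame.columns], dtype=float)
        wts = wts / wts.sum()
        return (frame.fillna(0.0) * wts).sum(axis=1)
    return frame.mean(axis=1)


def condition_scores(
    table: pd.DataFrame, condition: str, w: WeightVector | None = None
) -> pd.DataFrame:
    """Performance and robustness per strain for one condition."""
    w = w or WeightVector()
    sub = table[table["condition"] == condition]
    levels = sorted(sub["level"].unique())
    per_level = {}
    for lev in levels:
        oriented = orient_and_normalize(_level_slice(table, condition, lev))
        per_level[lev] = None if oriented is None else performance_level(oriented, w)
    perf = integrate_levels(per_level)
    if len(levels) >= 2:
        rob = robustness_strain(table, condition, w)
    else:
        rob = pd.Series(np.nan, index=perf.index)
    return pd.DataFrame({"performance": perf, "robustness": rob})


def rank_condition(scores: pd.Series) -> pd.DataFrame:
    """Rank strains by descending score (1 = best, average ties).

    Missing scores rank last (sharing average last ranks); the decile
    ranking value is ceil(10 * rank / n).
    """
    filled = scores.fillna(-np.inf)
    ranks = filled.rank(ascending=False, method="average")
    n = len(scores)
    ranking_value = np.ceil(10.0 * ranks / n).astype(int)
    return pd.DataFrame(
        {"score": scores, "rank": ranks, "ranking_value": ranking_value}
    ).sort_values("rank")


def ranking_table(
    table: pd.DataFrame, w: WeightVector | None = None
) -> pd.DataFrame:
    """All per-condition rankings for both score types (long format)."""
    w = w or WeightVector()
    rows = []
    for cond in sorted(table["condition"].unique()):
        sc = condition_scores(table, cond, w)
        for score_type in ("performance", "robustness"):
            rk = rank_condition(sc[score_type])
            rk = rk.reset_index().rename(columns={"index": "strain"})
            rk["condition"] = cond
            rk["score_type"] = score_type
            rows.append(rk)
    return pd.concat(rows, ignore_index=True)


def top_frequency(rankings: pd.DataFrame, k: int = 10) -> pd.Series:
    """Per-strain count of top-k appearances over all condition x score-type
    rankings (used to sort the summary)."""
    top = rankings[rankings["rank"] <= k]
    counts = top.groupby("strain").size()
    all_strains = rankings["strain"].unique()
    return counts.reindex(all_strains, fill_value=0).sort_values(ascending=False)


def rank_variability(
    table: pd.DataFrame,
    condition: str,
    score_type: str = "performance",
    n_weight_samples: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank distribution per strain under Dirichlet(1,..,1) weight samples.

    Returns per-strain rank quantiles (q05..q95) and the probability of
    falling in each decile ranking-value bin (columns bin_1..bin_10).
    """
    if n_weight_samples < 1:
        raise ValueError("n_weight_samples must be >= 1")
    rng = np.random.default_rng(seed)
    samples = rng.dirichlet(np.ones(len(PARAM_FIELDS)), size=n_weight_samples)
    all_ranks = []
    for wrow in samples:
        sc = condition_scores(table, condition, WeightVector(wrow))
        rk = rank_condition(sc[score_type])["rank"]
        all_ranks.append(rk)
    mat = pd.DataFrame(all_ranks)  # samples x strains
    n = mat.shape[1]
    bins = np.ceil(10.0 * mat / n).astype(int)
    out = pd.DataFrame(index=mat.columns)
    for q in (0.05, 0.25, 0.5, 0.75, 0.95):
        out[f"q{int(q * 100):02d}"] = mat.quantile(q)
    for b in range(1, 11):
        out[f"bin_{b}"] = (bins == b).mean()
    out.index.name = "strain"
    return out.sort_values("q50")


def parameter_influence(
    table: pd.DataFrame,
    bump: float = 0.25,
    score_type: str = "performance",
    conditions: list[str] | None = None,
) -> pd.DataFrame:
    """PI scores: rank change when one parameter is up-weighted.

    Baseline is equal weights; raw PI(strain, param) = baseline rank minus
    the rank when that parameter's weight is raised by ``bump`` (then
    renormalized) — positive means the strain moves up the table.  Entries
    are normalized by the global maximum absolute raw PI over all parameters
    and conditions, so the extreme entry is ±1 (all-zero profiles stay 0).
    Returns a strains x (condition, parameter) frame.
    """
    if bump <= 0:
        raise ValueError("bump must be > 0")
    conditions = conditions or sorted(table["condition"].unique())
    base_w = WeightVector()
    cols = {}
    for cond in conditions:
        base_rank = rank_condition(condition_scores(table, cond, base_w)[score_type])["rank"]
        for ki, k in enumerate(PARAM_FIELDS):
            warr = np.asarray(base_w.w).copy()
            warr[ki] += bump
            rk = rank_condition(condition_scores(table, cond, WeightVector(warr))[score_type])["rank"]
            cols[(cond, k)] = (base_rank - rk).reindex(base_rank.index)
    pi = pd.DataFrame(cols)
    pi.columns = pd.MultiIndex.from_tuples(pi.columns, names=["condition", "parameter"])
    m = np.nanmax(np.abs(pi.to_numpy())) if pi.size else 0.0
    if m > 0:
        pi = pi / m
    return pi


def pi_correlation(pi: pd.DataFrame, strain_a: str, strain_b: str) -> tuple[float, float]:
    """Spearman correlation of two strains' flattened PI profiles.

    Returns (rho, p); (nan, nan) when either profile is constant.
    """
    a = pi.loc[strain_a].to_numpy(dtype=float)
    b = pi.loc[strain_b].to_numpy(dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3 or np.std(a[ok]) == 0 or np.std(b[ok]) == 0:
        return (math.nan, math.nan)
    rho, p = stats.spearmanr(a[ok], b[ok])
    return float(rho), float(p)
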
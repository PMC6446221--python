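"""Cohort-level comparative statistics on rankings, genetic features and
metabolome groups.

Rank-based two-group (Wilcoxon rank-sum) and k-group (Kruskal-Wallis)
comparisons with Benjamini-Hochberg FDR control across a family of tests;
Spearman correlation matrices with Bonferroni adjustment; metabolite group
scores (mean signed z within pathway/class per strain) and the derived
per-group strain rankings.  Related strains sharing a bin group (e.g. the
Brazilian bioethanol strains) are collapsed to one pseudo-observation
before group tests to avoid pseudo-replication.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bin_strains",
    "compare_two",
    "compare_many",
    "bh_fdr",
    "spearman_matrix",
    "metabolome_group_scores",
    "euclidean_linkage",
]


def bin_strains(
    values: pd.Series,
    metadata: pd.DataFrame,
    group_col: str = "category",
    agg: str = "median",
) -> pd.DataFrame:
    """Collapse strains sharing a bin_group to one pseudo-observation.

    ``values`` is indexed by strain; ``metadata`` carries strain_id,
    ``group_col`` and bin_group (empty/NaN = not binned).  The binned
    pseudo-observation takes the median (or mean) of the member values and
    the group label of its members; other strains are untouched.  Returns a
    frame with columns value, group indexed by strain or bin id.
    """
    if agg not in ("median", "mean"):
        raise ValueError("agg must be 'median' or 'mean'")
    meta = metadata.set_index("strain_id")
    bin_groups = meta["bin_group"].fillna("").astype(str) if "bin_group" in meta else None
    rows = {}
    done_bins = set()
    for strain, val in values.items():
        if strain not in meta.index:
            raise KeyError(f"strain {strain!r} missing from metadata")
        bg = bin_groups.get(strain, "") if bin_groups is not None else ""
        if bg:
            if bg in done_bins:
                continue
            members = [s for s in values.index
                       if s in meta.index and bin_groups.get(s, "") == bg]
            mvals = values.loc[members].astype(float)
            v = float(mvals.median() if agg == "median" else mvals.mean())
            rows[f"bin:{bg}"] = {"value": v, "group": meta.loc[members[0], group_col]}
            done_bins.add(bg)
        else:
            rows[strain] = {"value": float(val), "group": meta.loc[strain, group_col]}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "observation"
    return out


def compare_two(
    grouped: pd.DataFrame, group_a: str, group_b: str
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) between two groups.

    Exact null distribution for small tie-free samples, normal approximation
    with tie correction otherwise.  Returns (U statistic, p).
    """
    x = grouped.loc[grouped["group"] == group_a, "value"].to_numpy(dtype=float)
    y = grouped.loc[grouped["group"] == group_b, "value"].to_numpy(dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (max(x.size, y.size) <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_many(grouped: pd.DataFrame) -> tuple[float, float]:
    """Kruskal-Wallis comparison across all groups (tie-corrected).

    All values identical returns (0, 1) rather than failing.
    """
    samples = [grp["value"].to_numpy(dtype=float)
               for _, grp in grouped.groupby("group")]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    allv = np.concatenate(samples)
    if np.all(allv == allv[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def spearman_matrix(
    features: pd.DataFrame, adjust: str = "bonferroni"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho over feature columns with multiplicity control.

    Observations are rows, features are columns; pairs with fewer than 3
    complete observations or a constant member get NaN.  Adjustment is
    Bonferroni over the number of tested pairs (BH available via
    ``adjust='bh'``).  Returns (rho matrix, adjusted-p matrix).
    """
    cols = list(features.columns)
    rho = pd.DataFrame(np.nan, index=cols, columns=cols)
    praw = {}
    np.fill_diagonal(rho.values, 1.0)
    for a, b in itertools.combinations(cols, 2):
        sub = features[[a, b]].dropna()
        if len(sub) < 3 or sub[a].nunique() == 1 or sub[b].nunique() == 1:
            continue
        r, p = stats.spearmanr(sub[a], sub[b])
        rho.loc[a, b] = rho.loc[b, a] = float(r)
        praw[(a, b)] = float(p)
    padj = pd.DataFrame(np.nan, index=cols, columns=cols)
    if praw:
        keys = list(praw)
        raw = np.array([praw[k] for k in keys])
        if adjust == "bonferroni":
            adj = np.minimum(raw * len(raw), 1.0)
        elif adjust == "bh":
            adj = multipletests(raw, method="fdr_bh")[1]
        else:
            raise ValueError("adjust must be 'bonferroni' or 'bh'")
        for (a, b), q in zip(keys, adj):
            padj.loc[a, b] = padj.loc[b, a] = float(q)
    return rho, padj


def metabolome_group_scores(
    abundances: pd.DataFrame,
    group_map: dict[str, str],
    production_sign: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Combined pathway/class contributions and per-group strain rankings.

    ``abundances``: metabolites x strains (positive).  Each metabolite is
    z-scored across strains; a group's score per strain is the mean signed z
    over its member metabolites — positive when the group's members are
    mostly above the across-strain mean.  ``production_sign=-1`` flips
    extracellular scores so production ranks above consumption.  Returns
    (strains x groups score matrix, same-shape rank matrix, 1 = top).
    """
    if (abundances <= 0).any().any():
        raise ValueError("abundances must be positive")
    logged = np.log10(abundances)
    z = logged.sub(logged.mean(axis=1), axis=0)
    sd = logged.std(axis=1, ddof=0)
    z = z.div(sd.replace(0, np.nan), axis=0).fillna(0.0)
    groups = sorted(set(group_map.values()))
    scores = {}
    for g in groups:
        members = [m for m, gg in group_map.items() if gg == g and m in z.index]
        if not members:
            continue
        scores[g] = production_sign * z.loc[members].mean(axis=0)
    score_frame = pd.DataFrame(scores)
    ranks = score_frame.rank(ascending=False, method="average")
    return score_frame, ranks


def euclidean_linkage(profile: pd.DataFrame) -> np.ndarray:
    """Plain Euclidean average linkage over the rows (plumbing for
    clustering strains by group profiles)."""
    return hierarchy.linkage(profile.to_numpy(), method="average", metric="euclidean")
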
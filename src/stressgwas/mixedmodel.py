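"""EMMA-style mixed-model association on strain rankings.

The phenotype is a strain ranking (optionally rank-based inverse-normal
transformed).  Variance components of the null model

    y = X0 b + g + e,   g ~ N(0, sigma_g^2 K),   e ~ N(0, sigma_e^2 I)

are estimated by REML over the single ratio delta = sigma_e^2 / sigma_g^2
using the spectral reduction of the restricted likelihood (one
eigendecomposition, then a 1-D grid search with local refinement).  Marker
tests use generalized least squares under the null components (P3D/EMMAX
default) or re-estimated components per marker (exact mode).  Significance
cutoffs come from the departure of observed p-values from the expected
uniform quantiles on a QQ plot, and gene-level p-values are the minimum
over markers/blocks overlapping the gene span plus its strand-aware
upstream regulatory region.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotypes import KinshipMatrix, LDBlock

__all__ = [
    "VarianceComponents",
    "SignificanceCutoff",
    "transform_phenotype",
    "reml_null",
    "assoc_scan",
    "assign_block_pvalues",
    "qq_cutoff",
    "gene_pvalues",
    "genomic_windows",
]


@dataclass
class VarianceComponents:
    delta: float          # sigma_e^2 / sigma_g^2
    sigma_g2: float
    sigma_e2: float
    reml_loglik: float


@dataclass
class SignificanceCutoff:
    source: str
    threshold: float      # largest p called significant; 0.0 = none
    eps_log10: float


def transform_phenotype(ranks: pd.Series, inverse_normal: bool = True) -> pd.Series:
    """Ranking to phenotype vector.

    Default applies a rank-based inverse-normal transform with offset 0.5
    quantiles (ties keep tied values); otherwise the raw rank numbers are
    used directly.
    """
    if not inverse_normal:
        return ranks.astype(float)
    r = ranks.rank(method="average")
    n = r.notna().sum()
    q = (r - 0.5) / n
    return pd.Series(stats.norm.ppf(q), index=ranks.index)


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------

def _spectral_parts(y, K, X0):
    """Project out fixed effects and eigendecompose the restricted kernel."""
    n = y.size
    q = X0.shape[1]
    # S(K + I)S keeps eigenvalues well defined for singular K
    Q, _ = np.linalg.qr(X0)
    S = np.eye(n) - Q @ Q.T
    B = S @ (K + np.eye(n)) @ S
    vals, vecs = np.linalg.eigh((B + B.T) / 2.0)
    # top n-q eigenpairs belong to the restricted space
    vals = vals[q:]
    vecs = vecs[:, q:]
    lam = np.clip(vals - 1.0, 0.0, None)
    eta = vecs.T @ y
    return lam, eta


def _reml_loglik(delta: float, lam: np.ndarray, eta: np.ndarray) -> float:
    m = lam.size
    d = lam + delta
    s = float(np.sum(eta**2 / d))
    return 0.5 * (m * (math.log(m / (2 * math.pi)) - 1.0 - math.log(s)) - float(np.sum(np.log(d))))


def reml_null(
    y: np.ndarray,
    K: KinshipMatrix | np.ndarray,
    X0: np.ndarray | None = None,
    grid: int = 100,
    bounds_log10: tuple[float, float] = (-5.0, 5.0),
) -> VarianceComponents:
    """REML variance components via EMMA's spectral 1-D objective.

    The restricted likelihood is maximized over log10 delta on a dense grid
    followed by bounded local refinement.  A flat (ridge) likelihood, as for
    K = I, yields a boundary/ridge estimate with a warning; the total
    variance sigma_g^2 (1 + delta) is identifiable regardless.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 5:
        raise ValueError("need at least 5 observations")
    Kv = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    vals = np.linalg.eigvalsh((Kv + Kv.T) / 2.0)
    if vals.min() < -1e-6:
        raise ValueError("kinship matrix is not positive semi-definite")
    if X0 is None:
        X0 = np.ones((n, 1))
    lam, eta = _spectral_parts(y, Kv, X0)

    log_d = np.linspace(*bounds_log10, grid)
    ll = np.array([_reml_loglik(10.0**g, lam, eta) for g in log_d])
    if ll.max() - ll.min() < 1e-8:
        warnings.warn("flat REML likelihood: delta unidentifiable (ridge); "
                      "returning grid midpoint", stacklevel=2)
        best = grid // 2
    else:
        best = int(np.argmax(ll))
    lo = log_d[max(best - 1, 0)]
    hi = log_d[min(best + 1, grid - 1)]
    res = optimize.minimize_scalar(
        lambda g: -_reml_loglik(10.0**g, lam, eta),
        bounds=(lo, hi), method="bounded",
    )
    delta = float(10.0**res.x)
    loglik = float(-res.fun)
    if loglik < ll[best]:  # keep the grid point if refinement did not help
        delta, loglik = float(10.0 ** log_d[best]), float(ll[best])
    m = lam.size
    sigma_g2 = float(np.sum(eta**2 / (lam + delta)) / m)
    return VarianceComponents(
        delta=delta, sigma_g2=sigma_g2, sigma_e2=delta * sigma_g2,
        reml_loglik=loglik,
    )


# ---------------------------------------------------------------------------
# association scan
# ---------------------------------------------------------------------------

def _whiten(Kv: np.ndarray, delta: float) -> np.ndarray:
    """Inverse Cholesky factor of H = K + delta I (up to scale)."""
    H = Kv + delta * np.eye(Kv.shape[0])
    L = np.linalg.cholesky(H)
    return np.linalg.inv(L)


def assoc_scan(
    y: np.ndarray,
    markers: np.ndarray,
    K: KinshipMatrix | np.ndarray,
    X0: np.ndarray | None = None,
    mode: str = "p3d",
    vc: VarianceComponents | None = None,
    source: str = "snp",
    unit_ids: list | None = None,
) -> pd.DataFrame:
    """Per-marker GLS association under the mixed model.

    ``markers`` is (n_markers x n_strains).  In the default P3D mode the
    null variance components are estimated once and reused for every marker;
    in exact mode delta is re-optimized per marker.  Constant markers are
    skipped (reported in the ``skipped`` attribute of the result frame).
    Returns a frame with unit, source, beta, se, p.
    """
    y = np.asarray(y, dtype=float)
    Kv = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    n = y.size
    if X0 is None:
        X0 = np.ones((n, 1))
    markers = np.atleast_2d(np.asarray(markers, dtype=float))
    if unit_ids is None:
        unit_ids = list(range(markers.shape[0]))
    if vc is None:
        vc = reml_null(y, Kv, X0)

    rows = []
    skipped = 0
    df_resid = n - X0.shape[1] - 1
    if mode == "p3d":
        W = _whiten(Kv, vc.delta)
        yw = W @ y
        X0w = W @ X0
    for j in range(markers.shape[0]):
        x = markers[j]
        if np.nanstd(x) == 0:
            skipped += 1
            continue
        x = np.where(np.isfinite(x), x, np.nanmean(x))
        if mode == "exact":
            vc_j = reml_null(y, Kv, np.column_stack([X0, x]))
            W = _whiten(Kv, vc_j.delta)
            yw = W @ y
            X0w = W @ X0
        Xw = np.column_stack([X0w, W @ x])
        beta, _, rank_, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        resid = yw - Xw @ beta
        rss = float(resid @ resid)
        XtX_inv = np.linalg.pinv(Xw.T @ Xw)
        sigma2 = rss / max(df_resid, 1)
        se = math.sqrt(max(sigma2 * XtX_inv[-1, -1], 0.0))
        b = float(beta[-1])
        if se > 0:
            t = b / se
            p = float(2.0 * stats.t.sf(abs(t), df_resid))
        else:
            p = 1.0
        rows.append({"unit": unit_ids[j], "source": source,
                     "beta": b, "se": se, "p": max(p, np.finfo(float).tiny)})
    out = pd.DataFrame(rows, columns=["unit", "source", "beta", "se", "p"])
    out.attrs["skipped"] = skipped
    out.attrs["vc"] = vc
    return out


def assign_block_pvalues(results: pd.DataFrame, blocks: list[LDBlock]) -> pd.DataFrame:
    """Expand block-representative results to per-member rows.

    The representative marker's test is assigned to every member of its
    block (the block is the tested unit).
    """
    rows = []
    by_unit = results.set_index("unit")
    for bi, blk in enumerate(blocks):
        if bi not in by_unit.index:
            continue
        r = by_unit.loc[bi]
        for m in blk.members:
            rows.append({"member": m, "block": bi, "beta": r["beta"],
                         "se": r["se"], "p": r["p"], "source": r["source"]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# significance cutoff and gene assignment
# ---------------------------------------------------------------------------

def qq_cutoff(pvals, source: str = "snp", eps_log10: float = 0.5) -> SignificanceCutoff:
    """QQ-departure significance threshold.

    P-values are sorted ascending; the expected quantile at rank i is
    i/(m+1).  Walking from the most significant, the longest prefix where
    -log10 p_obs >= -log10 p_exp + eps_log10 defines the significant set;
    the threshold is the largest observed p in that prefix (0.0 sentinel
    when the prefix is empty: nothing significant).
    """
    p = np.sort(np.asarray(pvals, dtype=float))
    m = p.size
    if m < 20:
        raise ValueError("need at least 20 p-values for a QQ cutoff")
    expected = np.arange(1, m + 1) / (m + 1)
    ok = -np.log10(p) >= -np.log10(expected) + eps_log10
    if not ok[0]:
        return SignificanceCutoff(source=source, threshold=0.0, eps_log10=eps_log10)
    stop = int(np.argmin(ok)) if not ok.all() else m
    return SignificanceCutoff(source=source, threshold=float(p[stop - 1]), eps_log10=eps_log10)


def gene_pvalues(
    results: pd.DataFrame,
    genes: pd.DataFrame,
    upstream_bp: int = 800,
) -> pd.DataFrame:
    """Gene-level p per source: min p over units overlapping the gene span
    plus its strand-aware upstream region.

    ``results`` must carry chrom/start/end for every tested unit (a point
    marker is the interval [pos, pos+1)).  Genes with no overlapping unit
    get NaN.  The upstream extension is [start-upstream_bp, start) on '+'
    genes and [end, end+upstream_bp) on '-' genes.
    """
    need = {"chrom", "start", "end", "p", "source"}
    if not need <= set(results.columns):
        raise ValueError(f"results must have columns {sorted(need)}")
    out_rows = []
    for _, g in genes.iterrows():
        if g["strand"] == "+":
            span_start = g["start"] - upstream_bp
            span_end = g["end"]
        else:
            span_start = g["start"]
            span_end = g["end"] + upstream_bp
        hit = results[
            (results["chrom"] == g["chrom"])
            & (results["start"] < span_end)
            & (results["end"] > span_start)
        ]
        row = {"gene_id": g["gene_id"]}
        for src, grp in hit.groupby("source"):
            row[f"p_{src}"] = float(grp["p"].min())
        out_rows.append(row)
    out = pd.DataFrame(out_rows)
    for src in results["source"].unique():
        if f"p_{src}" not in out.columns:
            out[f"p_{src}"] = np.nan
    return out


def genomic_windows(
    results: pd.DataFrame,
    cutoff: SignificanceCutoff,
    window: int = 50_000,
) -> pd.DataFrame:
    """Counts of significant units per non-overlapping genomic window.

    Units are bucketed by the window containing their start coordinate;
    the table is sorted by descending count (hot spots first).
    """
    sig = results[(results["p"] <= cutoff.threshold) & (cutoff.threshold > 0)]
    if sig.empty:
        return pd.DataFrame(columns=["chrom", "window_start", "count"])
    buckets = (sig["start"] // window) * window
    counts = (
        sig.assign(window_start=buckets)
        .groupby(["chrom", "window_start"])
        .size()
        .rename("count")
        .reset_index()
        .sort_values(["count", "chrom", "window_start"], ascending=[False, True, True])
        .reset_index(drop=True)
    )
    return counts
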
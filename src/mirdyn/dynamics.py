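"""Expression-dynamics analyses for mature/pri-miRNA time courses.

The central model treats the mature miRNA change rate between two consecutive
time windows as the balance of production and first-order decay:

    z ~ a*x + b*y + c

where, for each consecutive window pair, ``x`` is the mature level (RPTS) in
the first window, ``y`` is the transcription proxy (pri-miRNA upstream read
density) in the second window, and ``z`` is the mature-level difference
(second − first).  The coefficient on ``x`` estimates (minus) the degradation
rate; the coefficient on ``y`` the production efficiency per unit of
transcription.  Around this sit profile clustering (z-scores + k-means),
prediction error rates, log-linear half-life fits, a 5' nucleotide coefficient
comparison, and the clustered-miRNA change-rate ANOVA with Benjamini-Hochberg
correction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .popgen import KSResult, ks_one_tailed
from .windows import TimeWindow, windows_from_labels

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterResult",
    "FilterThresholds",
    "FilterReport",
    "KineticFit",
    "HalfLifeEstimate",
    "FivePrimeComparison",
    "zscore_profiles",
    "kmeans_profiles",
    "kmeans_elbow",
    "prepare_cluster_profiles",
    "filter_regression_genes",
    "aggregate_pri_density",
    "build_regression_points",
    "fit_kinetic_regression",
    "fit_per_gene",
    "predict_change_rates",
    "pooled_prediction_r2",
    "prediction_error_rates",
    "estimate_half_life",
    "half_life_table",
    "compare_coefficients_by_5p_nt",
    "change_rates",
    "cluster_change_anova",
]


def _windows_of(df: pd.DataFrame) -> list[TimeWindow]:
    return windows_from_labels(list(df.columns))


# ---------------------------------------------------------------------------
# Profiles and clustering


def zscore_profiles(mat: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-scores (mean 0, SD 1, ddof = 0) across time windows.

    Zero-variance rows cannot be scaled and are dropped with a logged warning.
    """
    if mat.shape[1] < 2:
        raise ValueError("z-scores need at least two time windows")
    values = mat.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=0)
    flat = sd == 0
    if flat.any():
        logger.warning("dropping %d zero-variance profiles: %s",
                       int(flat.sum()), list(mat.index[flat][:5]))
    kept = values[~flat]
    z = (kept - kept.mean(axis=1, keepdims=True)) / sd[~flat][:, None]
    return pd.DataFrame(z, index=mat.index[~flat], columns=mat.columns)


@dataclass
class ClusterResult:
    k: int
    assignments: pd.Series               # gene -> cluster id (0-based)
    centroids: np.ndarray                # (k, n_windows)
    wss: float                           # within-cluster sum of squares


def kmeans_profiles(
    zmat: pd.DataFrame, k: int, restarts: int = 10, seed: int = 0
) -> ClusterResult:
    """Euclidean k-means on profile rows; best of ``restarts`` seeded inits."""
    if k > len(zmat):
        raise ValueError(f"k={k} exceeds number of genes ({len(zmat)})")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(zmat.to_numpy(dtype=float))
    return ClusterResult(
        k=k,
        assignments=pd.Series(labels, index=zmat.index, name="cluster"),
        centroids=km.cluster_centers_,
        wss=float(km.inertia_),
    )


def kmeans_elbow(
    zmat: pd.DataFrame, ks: Sequence[int], restarts: int = 10, seed: int = 0
) -> pd.Series:
    """Within-cluster sum of squares per candidate k, for elbow plots."""
    return pd.Series(
        {k: kmeans_profiles(zmat, k, restarts=restarts, seed=seed).wss for k in ks},
        name="wss",
    ).rename_axis("k")


def prepare_cluster_profiles(
    rpts: pd.DataFrame,
    paralog_groups: Mapping[str, Sequence[str]] | None = None,
    min_mean_rpts: float = 5.0,
) -> pd.DataFrame:
    """Preprocess clustered-miRNA profiles for per-cluster comparisons.

    Same-sequence paralogs (which cannot be distinguished by reads) are
    averaged into one profile named after the group; genes whose all-window
    mean RPTS falls below ``min_mean_rpts`` are dropped.
    """
    df = rpts.copy()
    if paralog_groups:
        for group_name, members in paralog_groups.items():
            present = [m for m in members if m in df.index]
            if not present:
                continue
            avg = df.loc[present].mean(axis=0)
            df = df.drop(index=present)
            df.loc[group_name] = avg
    low = df.mean(axis=1) < min_mean_rpts
    if low.any():
        logger.info("cluster preprocessing: dropped %d genes with mean RPTS < %g",
                    int(low.sum()), min_mean_rpts)
    return df.loc[~low]


# ---------------------------------------------------------------------------
# Regression gene filters


@dataclass(frozen=True)
class FilterThresholds:
    """Gene filters applied before the kinetic regression (study defaults)."""

    maternal_first_window_share: float = 0.30   # first-window share of summed RPTS
    pri_min_density: float = 1.0                # upstream density must exceed this ...
    pri_min_windows: int = 1                    # ... in at least this many windows
    mature_min_rpts: float = 10.0               # mature RPTS must exceed this ...
    mature_min_windows: int = 5                 # ... in at least this many windows
    multimapper_max: float = 0.20               # reject genes above this fraction


@dataclass
class FilterReport:
    kept: list[str]
    removed: dict[str, list[str]] = field(default_factory=dict)

    def log(self) -> None:
        for rule, genes in self.removed.items():
            logger.info("filter %s removed %d genes", rule, len(genes))


def filter_regression_genes(
    mature: pd.DataFrame,
    pri: pd.DataFrame,
    thresholds: FilterThresholds = FilterThresholds(),
    multimapper_fraction: pd.Series | None = None,
) -> FilterReport:
    """Apply the regression inclusion filters; returns kept genes and casualties.

    Removed are genes that are maternally dominated (first-window RPTS share
    above the threshold), lack detectable transcription (upstream density never
    above ``pri_min_density``), are expressed too narrowly (mature RPTS above
    ``mature_min_rpts`` in fewer than ``mature_min_windows`` windows), or have
    too many multi-mapping reads.
    """
    if list(mature.columns) != list(pri.columns):
        raise ValueError("mature and pri matrices are on different window grids")
    t = thresholds
    pri = pri.reindex(mature.index).fillna(0.0)
    removed: dict[str, list[str]] = {}

    totals = mature.sum(axis=1)
    share = mature.iloc[:, 0].where(totals > 0, 0.0) / totals.replace(0, np.nan)
    share = share.fillna(0.0)
    maternal = share > t.maternal_first_window_share
    removed["maternal_share"] = list(mature.index[maternal])

    pri_ok = (pri > t.pri_min_density).sum(axis=1) >= t.pri_min_windows
    removed["pri_density"] = list(mature.index[~pri_ok])

    mature_ok = (mature > t.mature_min_rpts).sum(axis=1) >= t.mature_min_windows
    removed["mature_level"] = list(mature.index[~mature_ok])

    if multimapper_fraction is not None:
        mm = multimapper_fraction.reindex(mature.index).fillna(0.0)
        removed["multimapper"] = list(mature.index[mm > t.multimapper_max])
    else:
        removed["multimapper"] = []

    bad = set().union(*removed.values())
    report = FilterReport(kept=[g for g in mature.index if g not in bad], removed=removed)
    report.log()
    return report


# ---------------------------------------------------------------------------
# Pri-density aggregation and regression points


def aggregate_pri_density(
    fine: pd.DataFrame, target_bounds: Sequence[tuple[float, float]]
) -> pd.DataFrame:
    """Re-grid a fine-window density table to target windows by unweighted mean.

    Each target window must be exactly tiled by fine windows (this mirrors
    averaging three 2 h windows into one 6 h window).
    """
    fine_wins = _windows_of(fine)
    out = {}
    for s, e in target_bounds:
        tw = TimeWindow(float(s), float(e))
        covered = [w for w in fine_wins if w.start >= tw.start and w.end <= tw.end]
        span = sorted((w.start, w.end) for w in covered)
        ok = bool(span) and span[0][0] == tw.start and span[-1][1] == tw.end
        ok = ok and all(a[1] == b[0] for a, b in zip(span, span[1:]))
        if not ok:
            raise ValueError(f"target window {tw.label} is not tiled by the fine grid")
        out[tw.label] = fine[[w.label for w in covered]].mean(axis=1)
    return pd.DataFrame(out, index=fine.index)


def build_regression_points(
    mature: pd.DataFrame, pri: pd.DataFrame, per_hour: bool = False
) -> pd.DataFrame:
    """One (x, y, z) triple per gene per consecutive window pair.

    ``z`` is the raw mature-level difference (second − first window) by
    default; ``per_hour=True`` divides by the midpoint gap, turning z into a
    change rate per hour (useful when window widths differ).
    """
    if list(mature.columns) != list(pri.columns):
        raise ValueError("mature and pri matrices are on different window grids")
    wins = _windows_of(mature)
    if len(wins) < 2:
        raise ValueError("need at least two windows to form pairs")
    pri = pri.reindex(mature.index)
    rows = []
    for pair, (w1, w2) in enumerate(zip(wins, wins[1:])):
        gap = w2.midpoint - w1.midpoint
        x = mature[w1.label]
        y = pri[w2.label]
        z = mature[w2.label] - mature[w1.label]
        if per_hour:
            z = z / gap
        for gene in mature.index:
            rows.append(
                {
                    "gene": gene,
                    "pair": pair,
                    "window1": w1.label,
                    "window2": w2.label,
                    "x": float(x[gene]),
                    "y": float(y[gene]),
                    "z": float(z[gene]),
                    "gap_h": gap,
                    "window2_width_h": w2.width,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Kinetic regression


@dataclass
class KineticFit:
    a: float                              # coefficient on x (mature level)
    b: float                              # coefficient on y (upstream density)
    c: float                              # intercept
    r2: float
    n_points: int
    scope: str                            # "global" or a gene id
    ok: bool = True


def _ols_fit(x: np.ndarray, y: np.ndarray, z: np.ndarray, scope: str) -> KineticFit:
    X = np.column_stack([x, y, np.ones_like(x)])
    if len(z) < 3:
        raise ValueError(f"{scope}: need >= 3 points for a 3-parameter fit, got {len(z)}")
    coef, _, rank, _ = np.linalg.lstsq(X, z, rcond=None)
    if rank < 3:
        logger.warning("%s: rank-deficient design (rank %d); fit flagged", scope, rank)
        return KineticFit(math.nan, math.nan, math.nan, math.nan, len(z), scope, ok=False)
    resid = z - X @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((z - z.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else math.nan)
    return KineticFit(float(coef[0]), float(coef[1]), float(coef[2]), r2, len(z), scope)


def fit_kinetic_regression(points: pd.DataFrame, scope: str = "global") -> KineticFit | pd.DataFrame:
    """Ordinary least squares of z ~ a·x + b·y + c.

    ``scope="global"`` pools all points into one plane; ``scope="per_gene"``
    fits each gene separately and returns a table with the conventional column
    names (Coef_mature_Level, Coef_Updensity, intercept, r2).
    """
    if scope == "global":
        return _ols_fit(
            points["x"].to_numpy(), points["y"].to_numpy(), points["z"].to_numpy(), "global"
        )
    if scope == "per_gene":
        return fit_per_gene(points)
    raise ValueError(f"unknown scope {scope!r}")


def fit_per_gene(points: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for gene, sub in points.groupby("gene", sort=False):
        fit = _ols_fit(
            sub["x"].to_numpy(), sub["y"].to_numpy(), sub["z"].to_numpy(), str(gene)
        )
        rows.append(
            {
                "gene": gene,
                "Coef_mature_Level": fit.a,
                "Coef_Updensity": fit.b,
                "intercept": fit.c,
                "r2": fit.r2,
                "n_points": fit.n_points,
                "ok": fit.ok,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def predict_change_rates(
    fits: KineticFit | pd.DataFrame, points: pd.DataFrame
) -> pd.Series:
    """Predicted z for each point, from a global fit or a per-gene fit table."""
    if isinstance(fits, KineticFit):
        pred = fits.a * points["x"] + fits.b * points["y"] + fits.c
        return pred.rename("predicted")
    table = fits.loc[fits["ok"]] if "ok" in fits.columns else fits
    a = points["gene"].map(table["Coef_mature_Level"])
    b = points["gene"].map(table["Coef_Updensity"])
    c = points["gene"].map(table["intercept"])
    return (a * points["x"] + b * points["y"] + c).rename("predicted")


def pooled_prediction_r2(fits: KineticFit | pd.DataFrame, points: pd.DataFrame) -> float:
    """Squared Pearson correlation of pooled predicted vs observed change rates."""
    pred = predict_change_rates(fits, points)
    mask = pred.notna()
    r, _ = stats.pearsonr(pred[mask], points.loc[mask, "z"])
    return float(r * r)


def prediction_error_rates(
    points: pd.DataFrame,
    predictions: pd.Series,
    mature: pd.DataFrame,
    min_level: float = 10.0,
) -> pd.DataFrame:
    """Per-point percentage prediction errors.

    error rate = (predicted − observed change rate) × window size × 100
    / mature level, where the window size and mature level are those of the
    second window of the pair.  Points whose mature level in that window is
    below ``min_level`` (or zero) are flagged excluded.
    """
    level = np.array(
        [mature.at[g, w] for g, w in zip(points["gene"], points["window2"])], dtype=float
    )
    width = points["window2_width_h"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        err = (predictions.to_numpy() - points["z"].to_numpy()) * width * 100.0 / level
    out = points[["gene", "pair", "window1", "window2", "z"]].copy()
    out["predicted"] = predictions.to_numpy()
    out["mature_level"] = level
    out["error_rate_pct"] = err
    out["excluded"] = (level < min_level) | (level == 0)
    return out


# ---------------------------------------------------------------------------
# Half-lives


@dataclass
class HalfLifeEstimate:
    """Log-linear first-order decay fit: ln(level) = ln(L0) − λ·t."""

    decay_rate: float                     # λ, per hour
    half_life: float                      # ln2/λ; +inf when λ <= 0
    r2: float
    n_points: int
    ok: bool = True


def estimate_half_life(
    levels: Sequence[float],
    times: Sequence[float],
    window_range: tuple[float, float] | None = None,
) -> HalfLifeEstimate:
    """Fit ln(level) against time (window midpoints) by least squares.

    Non-positive levels are dropped (they carry no log information); an
    estimate based on fewer than two positive points is flagged undefined.
    ``window_range`` restricts the fit to times within [lo, hi].
    """
    lv = np.asarray(levels, dtype=float)
    t = np.asarray(times, dtype=float)
    if lv.shape != t.shape:
        raise ValueError("levels and times must have equal length")
    mask = lv > 0
    if window_range is not None:
        lo, hi = window_range
        mask &= (t >= lo) & (t <= hi)
    lv, t = lv[mask], t[mask]
    if lv.size < 2 or np.unique(t).size < 2:
        return HalfLifeEstimate(math.nan, math.nan, math.nan, int(lv.size), ok=False)
    res = stats.linregress(t, np.log(lv))
    lam = -float(res.slope)
    half_life = math.log(2) / lam if lam > 0 else math.inf
    r2 = float(res.rvalue**2)
    return HalfLifeEstimate(lam, half_life, r2, int(lv.size))


def half_life_table(
    mature: pd.DataFrame, window_range: tuple[float, float] | None = None
) -> pd.DataFrame:
    """Half-life estimates for every gene of a mature-level table."""
    wins = _windows_of(mature)
    mids = np.array([w.midpoint for w in wins])
    rows = []
    for gene in mature.index:
        est = estimate_half_life(mature.loc[gene].to_numpy(), mids, window_range)
        rows.append(
            {
                "gene": gene,
                "decay_rate_per_h": est.decay_rate,
                "half_life_h": est.half_life,
                "r2": est.r2,
                "n_points": est.n_points,
                "ok": est.ok,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


# ---------------------------------------------------------------------------
# 5' nucleotide comparison


@dataclass
class FivePrimeComparison:
    n_u: int
    n_other: int
    mean_u: float
    mean_other: float
    median_u: float
    median_other: float
    ks: KSResult


def compare_coefficients_by_5p_nt(
    per_gene_fits: pd.DataFrame, five_prime_nt: pd.Series
) -> FivePrimeComparison:
    """Compare mature-level coefficients between 5'-U and non-5'-U miRNAs.

    Mature miRNAs beginning with uridine bind Argonaute's MID pocket most
    tightly and are expected to decay more slowly, i.e. to carry higher
    (less negative) coefficients.  Tested with a one-tailed two-sample KS
    (alternative: the 5'-U coefficient distribution is stochastically larger).
    """
    fits = per_gene_fits.loc[per_gene_fits["ok"]] if "ok" in per_gene_fits.columns else per_gene_fits
    nt = five_prime_nt.reindex(fits.index).str.upper().str.replace("T", "U")
    is_u = nt == "U"
    coef_u = fits.loc[is_u, "Coef_mature_Level"].dropna()
    coef_other = fits.loc[~is_u & nt.notna(), "Coef_mature_Level"].dropna()
    if coef_u.empty or coef_other.empty:
        raise ValueError("both 5'-U and non-5'-U groups must be nonempty")
    ks = ks_one_tailed(coef_u, coef_other, alternative="greater")
    return FivePrimeComparison(
        n_u=len(coef_u),
        n_other=len(coef_other),
        mean_u=float(coef_u.mean()),
        mean_other=float(coef_other.mean()),
        median_u=float(coef_u.median()),
        median_other=float(coef_other.median()),
        ks=ks,
    )


# ---------------------------------------------------------------------------
# Clustered-miRNA change-rate ANOVA


def change_rates(
    rpts_replicates: Mapping[str, pd.DataFrame], per_hour: bool = False
) -> pd.DataFrame:
    """Tidy per-replicate change rates for every consecutive window pair."""
    rows = []
    for rep, df in rpts_replicates.items():
        wins = _windows_of(df)
        for pair, (w1, w2) in enumerate(zip(wins, wins[1:])):
            delta = df[w2.label] - df[w1.label]
            if per_hour:
                delta = delta / (w2.midpoint - w1.midpoint)
            for gene, val in delta.items():
                rows.append(
                    {
                        "gene": gene,
                        "replicate": rep,
                        "pair": pair,
                        "window_pair": f"{w1.label}->{w2.label}",
                        "change": float(val),
                    }
                )
    return pd.DataFrame(rows)


def cluster_change_anova(
    rpts_replicates: Mapping[str, pd.DataFrame],
    cluster_membership: Mapping[str, str],
    per_hour: bool = False,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Test whether cluster members change at different rates per window pair.

    For each genomic miRNA cluster and each consecutive window pair, a one-way
    ANOVA compares the per-replicate change rates across cluster members; all
    (cluster x window-pair) p-values are Benjamini-Hochberg adjusted together
    and flagged significant at adjusted p < ``alpha``.  Clusters with fewer
    than two members are skipped with a warning.
    """
    if len(rpts_replicates) < 2:
        raise ValueError("need at least two replicates for ANOVA")
    tidy = change_rates(rpts_replicates, per_hour=per_hour)
    tidy["cluster"] = tidy["gene"].map(cluster_membership)
    tidy = tidy.dropna(subset=["cluster"])

    rows = []
    for (cluster, pair_label), sub in tidy.groupby(["cluster", "window_pair"], sort=False):
        groups = [g["change"].to_numpy() for _, g in sub.groupby("gene", sort=False)]
        if len(groups) < 2:
            logger.warning("cluster %s has < 2 members; skipped", cluster)
            continue
        flat = np.concatenate(groups)
        if np.allclose(flat, flat[0]):
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = stats.f_oneway(*groups)
            f_stat, p = float(f_stat), float(p)
        rows.append(
            {
                "cluster": cluster,
                "window_pair": pair_label,
                "n_members": len(groups),
                "F": f_stat,
                "p": p,
                "member_means": {
                    str(g): float(s["change"].mean()) for g, s in sub.groupby("gene", sort=False)
                },
            }
        )
    result = pd.DataFrame(rows)
    if result.empty:
        return result
    result["p_adj"] = multipletests(result["p"].to_numpy(), method="fdr_bh")[1]
    result["significant"] = result["p_adj"] < alpha
    return result
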
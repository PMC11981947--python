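"""Pairwise like-to-like statistics.

Covers: per-presynaptic cohort mean comparisons with paired t-tests,
presyn-centred binned effect curves with bootstrap errors, the three
mixed-model families (Tweedie for L_d, Poisson for N_syn, Poisson with a
log L_d offset for the synapse conversion rate N_syn / L_d), conditional
like-to-like coefficients per projection type with data-quality filters,
the two-step residual regression of similarity on synaptic anatomy, and
similarity-by-somatic-distance profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from liketolike.glmm import GlmmResult, benjamini_hochberg, fit_glmm

#: minimum postsynaptic targets per presyn for cohort mean comparisons
MIN_TARGETS_PER_PRESYN = 10

#: projection inclusion filters for reported like-to-like coefficients
MIN_SYNAPSES_PER_PROJECTION = 30
MIN_PRESYN_PER_PROJECTION = 5
MAX_PRESYN_SYNAPSE_SHARE = 0.5

#: binned-effect inclusion: more than ten pairs and more than ten presyn
MIN_PAIRS_PER_BIN = 10
MIN_PRESYN_PER_BIN = 10


# ---------------------------------------------------------------------------
# cohort mean comparisons
# ---------------------------------------------------------------------------

def cohort_mean_test(pair_records: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Paired t-tests of per-presyn mean similarity between cohorts.

    For each projection type and each cohort contrast (connected vs
    adp_control, connected vs same_region_control, adp_control vs
    same_region_control), presynaptic neurons with more than
    ``MIN_TARGETS_PER_PRESYN`` postsynaptic targets contribute one mean per
    cohort; a two-sided paired t-test compares the cohort means across
    presynaptic neurons, and p-values are Benjamini-Hochberg adjusted within
    the returned table.
    """
    contrasts = [
        ("connected", "adp_control"),
        ("connected", "same_region_control"),
        ("adp_control", "same_region_control"),
    ]
    rows = []
    for proj, sub in pair_records.groupby("projection"):
        n_targets = (
            sub[sub["cohort"] == "connected"].groupby("pre_id")["post_id"].count()
        )
        eligible = set(n_targets[n_targets > MIN_TARGETS_PER_PRESYN].index)
        means = (
            sub[sub["pre_id"].isin(eligible)]
            .groupby(["pre_id", "cohort"])[metric]
            .mean()
            .unstack()
        )
        for a, b in contrasts:
            if a not in means.columns or b not in means.columns:
                rows.append(
                    {"projection": proj, "cohort_a": a, "cohort_b": b,
                     "n_presyn": 0, "mean_a": np.nan, "mean_b": np.nan,
                     "t": np.nan, "p": np.nan, "testable": False}
                )
                continue
            paired = means[[a, b]].dropna()
            if len(paired) < 2:
                rows.append(
                    {"projection": proj, "cohort_a": a, "cohort_b": b,
                     "n_presyn": len(paired), "mean_a": np.nan, "mean_b": np.nan,
                     "t": np.nan, "p": np.nan, "testable": False}
                )
                continue
            diff = paired[a] - paired[b]
            if np.allclose(diff, 0):
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_rel(paired[a], paired[b])
            rows.append(
                {"projection": proj, "cohort_a": a, "cohort_b": b,
                 "n_presyn": len(paired),
                 "mean_a": paired[a].mean(), "mean_b": paired[b].mean(),
                 "t": float(t), "p": float(p), "testable": True}
            )
    cols = ["projection", "cohort_a", "cohort_b", "n_presyn", "mean_a",
            "mean_b", "t", "p", "testable"]
    out = pd.DataFrame(rows, columns=cols)
    out["p_adj"] = benjamini_hochberg(out["p"]) if len(out) else np.nan
    return out


# ---------------------------------------------------------------------------
# centred binned effect curves
# ---------------------------------------------------------------------------

@dataclass
class BinnedEffect:
    x_metric: str
    y_metric: str
    mode: str  # "Ld" | "density"
    bin_edges: np.ndarray
    bin_mean: np.ndarray
    bin_se: np.ndarray  # bootstrap s.e., n_boot resamples
    n_pairs: np.ndarray
    n_presyn: np.ndarray
    included: np.ndarray  # bin passes the pair/presyn inclusion rule
    table: pd.DataFrame = field(default_factory=pd.DataFrame)


def centered_binned_effect(
    pair_records: pd.DataFrame,
    x_metric: str,
    y_metric: str = None,
    mode: str = "Ld",
    bins: int | np.ndarray = 10,
    n_boot: int = 1000,
    seed: int = 0,
) -> BinnedEffect:
    """Presyn-centred binned relationship between similarity and anatomy.

    mode "Ld": restrict to pairs with no synapses; y is L_d. mode "density":
    restrict to pairs with L_d > 0; y is N_syn / L_d. Per presynaptic neuron
    the mean of both axes is subtracted (neurons with fewer than two pairs
    are dropped); pairs are binned by centred x and the mean centred y per
    bin is reported with a bootstrap standard error over pair resampling.
    Bins with <= 10 pairs or <= 10 distinct presynaptic neurons are flagged
    excluded.
    """
    if mode == "Ld":
        sub = pair_records[pair_records["n_syn"] == 0].copy()
        sub["_y"] = sub["L_d"]
        y_metric = y_metric or "L_d"
    elif mode == "density":
        sub = pair_records[pair_records["L_d"] > 0].copy()
        sub["_y"] = sub["n_syn"] / sub["L_d"]
        y_metric = y_metric or "n_syn/L_d"
    else:
        raise ValueError("mode must be 'Ld' or 'density'")

    counts = sub.groupby("pre_id")["post_id"].count()
    keep = counts[counts >= 2].index
    sub = sub[sub["pre_id"].isin(keep)].copy()

    grp = sub.groupby("pre_id")
    sub["dx"] = sub[x_metric] - grp[x_metric].transform("mean")
    sub["dy"] = sub["_y"] - grp["_y"].transform("mean")

    edges = (
        np.histogram_bin_edges(sub["dx"], bins=bins)
        if np.isscalar(bins)
        else np.asarray(bins, float)
    )
    which = np.clip(np.digitize(sub["dx"], edges) - 1, 0, len(edges) - 2)
    nb = len(edges) - 1

    def bin_means(dx_bin, dy):
        out = np.full(nb, np.nan)
        for k in range(nb):
            m = dx_bin == k
            if m.any():
                out[k] = dy[m].mean()
        return out

    mean = bin_means(which, sub["dy"].to_numpy())
    n_pairs = np.bincount(which, minlength=nb)
    n_presyn = np.array(
        [sub.loc[which == k, "pre_id"].nunique() for k in range(nb)]
    )

    rng = np.random.default_rng(seed)
    boot = np.full((n_boot, nb), np.nan)
    dxv = sub["dx"].to_numpy()
    yv = sub["_y"].to_numpy()
    xv = sub[x_metric].to_numpy()
    pre = sub["pre_id"].to_numpy()
    n = len(sub)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        bs = pd.DataFrame({"pre": pre[idx], "x": xv[idx], "y": yv[idx]})
        g = bs.groupby("pre")
        bdx = bs["x"] - g["x"].transform("mean")
        bdy = bs["y"] - g["y"].transform("mean")
        wb = np.clip(np.digitize(bdx, edges) - 1, 0, nb - 1)
        boot[b] = bin_means(wb, bdy.to_numpy())
    se = np.nanstd(boot, axis=0, ddof=1)

    included = (n_pairs > MIN_PAIRS_PER_BIN) & (n_presyn > MIN_PRESYN_PER_BIN)
    table = pd.DataFrame(
        {
            "bin_left": edges[:-1], "bin_right": edges[1:],
            "mean": mean, "se": se, "n_pairs": n_pairs,
            "n_presyn": n_presyn, "included": included,
        }
    )
    return BinnedEffect(
        x_metric=x_metric, y_metric=y_metric, mode=mode, bin_edges=edges,
        bin_mean=mean, bin_se=se, n_pairs=n_pairs, n_presyn=n_presyn,
        included=included, table=table,
    )


# ---------------------------------------------------------------------------
# GLMM specification and fitting
# ---------------------------------------------------------------------------

@dataclass
class GlmmSpec:
    """Specification of one like-to-like mixed model.

    response "L_d" uses the Tweedie family on all pairs; "N_syn" uses
    Poisson on all pairs; "N_syn_per_Ld" uses Poisson with a log L_d offset
    on pairs with L_d > 0 (the synapse conversion-rate model).
    """

    response: str  # "L_d" | "N_syn" | "N_syn_per_Ld"
    similarity: str = "feature_similarity"
    standardize: bool = False
    xi: float | None = None  # fix the Tweedie index; None profiles it
    interaction: bool = True  # include Sim x Proj (off: one pooled slope)


@dataclass
class GlmmFit:
    spec: GlmmSpec
    result: GlmmResult
    projections: list
    slope_table: pd.DataFrame  # per-projection conditional slopes
    n_pairs: int
    data_stats: pd.DataFrame  # per-projection n_pairs / n_presyn / n_synapses


def _design(pairs: pd.DataFrame, spec: GlmmSpec):
    """Fixed-effect design: intercept + Sim + Proj dummies + Sim x Proj."""
    sim = pairs[spec.similarity].to_numpy(float)
    if spec.standardize:
        sim = (sim - sim.mean()) / sim.std()
    projections = sorted(pairs["projection"].unique())
    ref = projections[0]
    cols = [np.ones(len(pairs)), sim]
    names = ["intercept", "sim"]
    for proj in projections[1:]:
        d = (pairs["projection"] == proj).to_numpy(float)
        cols.append(d)
        names.append(f"proj[{proj}]")
        if spec.interaction:
            cols.append(d * sim)
            names.append(f"sim:proj[{proj}]")
    return np.column_stack(cols), names, projections, ref


def fit_likelike_glmm(pair_records: pd.DataFrame, spec: GlmmSpec) -> GlmmFit:
    """Fit the specified like-to-like GLMM with presynaptic random intercepts.

    Random intercepts group presynaptic neurons within projection-by-
    proofread strata. Conditional like-to-like slopes (beta_1 + beta_3[k])
    per projection are extracted with delta-method standard errors and
    BH-adjusted Wald p-values.
    """
    pairs = pair_records.copy()
    if spec.response == "L_d":
        y = pairs["L_d"].to_numpy(float)
        family, offset, weights = "tweedie", None, None
    elif spec.response == "N_syn":
        y = pairs["n_syn"].to_numpy(float)
        family, offset, weights = "poisson", None, None
    elif spec.response == "N_syn_per_Ld":
        pairs = pairs[pairs["L_d"] > 0].copy()
        y = pairs["n_syn"].to_numpy(float)
        family = "poisson"
        offset = np.log(pairs["L_d"].to_numpy(float) / 1000.0)  # per mm
        weights = None
    else:
        raise ValueError(f"unknown response {spec.response!r}")

    X, names, projections, ref = _design(pairs, spec)
    proofread = pairs["proofread"] if "proofread" in pairs else "all"
    groups = (
        pairs["projection"].astype(str)
        + "|"
        + pd.Series(proofread, index=pairs.index).astype(str)
        + "|"
        + pairs["pre_id"].astype(str)
    ).to_numpy()
    result = fit_glmm(
        y, X, groups=groups, family=family, offset=offset,
        exog_names=names, xi=spec.xi, prior_weights=weights,
    )
    slope_table = _conditional_slopes(result, projections, ref)
    stats_rows = []
    for proj, sub in pairs.groupby("projection"):
        stats_rows.append(
            {
                "projection": proj,
                "n_pairs": len(sub),
                "n_presyn": sub["pre_id"].nunique(),
                "n_synapses": int(sub["n_syn"].sum()),
                "max_presyn_share": (
                    sub.groupby("pre_id")["n_syn"].sum().max() / max(sub["n_syn"].sum(), 1)
                ),
            }
        )
    return GlmmFit(
        spec=spec, result=result, projections=projections,
        slope_table=slope_table, n_pairs=len(pairs),
        data_stats=pd.DataFrame(stats_rows),
    )


def _conditional_slopes(result: GlmmResult, projections, ref) -> pd.DataFrame:
    """beta_1 + beta_3[k] with delta-method s.e. from the coefficient covariance."""
    names = result.exog_names
    cov = result.cov_params
    rows = []
    for proj in projections:
        c = np.zeros(len(names))
        c[names.index("sim")] = 1.0
        inter = f"sim:proj[{proj}]"
        if inter in names:
            c[names.index(inter)] = 1.0
        slope = float(c @ result.params)
        se = float(np.sqrt(c @ cov @ c))
        z = slope / se if se > 0 else np.nan
        p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append({"projection": proj, "slope": slope, "se": se, "z": z, "p": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = benjamini_hochberg(out["p"])
    return out


def extract_likelike_coefficients(fit: GlmmFit, apply_filters: bool = True) -> pd.DataFrame:
    """Per-projection conditional slopes after data-quality filters.

    A projection is reported only with more than 30 synapses, more than 5
    presynaptic neurons, and no single presynaptic neuron contributing more
    than half of its synapses. Filtered projections appear with
    ``reported = False`` and nan coefficients rather than silently vanishing.
    BH adjustment runs across the reported slopes.
    """
    merged = fit.slope_table.merge(fit.data_stats, on="projection", how="left")
    if apply_filters:
        ok = (
            (merged["n_synapses"] > MIN_SYNAPSES_PER_PROJECTION)
            & (merged["n_presyn"] > MIN_PRESYN_PER_PROJECTION)
            & (merged["max_presyn_share"] <= MAX_PRESYN_SYNAPSE_SHARE)
        )
    else:
        ok = pd.Series(True, index=merged.index)
    merged["reported"] = ok
    merged.loc[~ok, ["slope", "se", "z", "p"]] = np.nan
    merged["p_adj"] = benjamini_hochberg(merged["p"])
    merged["more_like_to_like"] = merged["slope"] > 0
    return merged


# ---------------------------------------------------------------------------
# residual anatomy regression
# ---------------------------------------------------------------------------

def residual_anatomy_regression(
    connected_pairs: pd.DataFrame,
    metrics,
    n_syn_col: str = "n_syn",
    cleft_col: str = "mean_cleft_volume",
    ld_col: str = "L_d",
) -> pd.DataFrame:
    """Two-step regression isolating synaptic anatomy from proximity.

    Step 1 regresses each similarity metric on L_d (OLS) and keeps the
    residuals; step 2 regresses those residuals on the synapse count and
    log10 mean cleft volume. Coefficients with s.e. and BH-adjusted p-values
    (across metrics, within each predictor) are returned. Constant
    predictors yield absent (nan) coefficients.
    """
    import statsmodels.api as sm

    rows = []
    for metric in np.atleast_1d(metrics):
        sub = connected_pairs[
            (connected_pairs[ld_col] > 0) & connected_pairs[cleft_col].notna()
        ].copy()
        y = sub[metric].to_numpy(float)
        step1 = sm.OLS(y, sm.add_constant(sub[ld_col].to_numpy(float))).fit()
        resid = step1.resid
        X2 = pd.DataFrame(
            {
                n_syn_col: sub[n_syn_col].to_numpy(float),
                "log10_cleft": np.log10(sub[cleft_col].to_numpy(float)),
            }
        )
        for pred in X2.columns:
            if X2[pred].nunique() <= 1:
                rows.append({"metric": metric, "predictor": pred, "coef": np.nan,
                             "se": np.nan, "p": np.nan, "n": len(sub)})
        usable = [c for c in X2.columns if X2[c].nunique() > 1]
        if usable:
            step2 = sm.OLS(resid, sm.add_constant(X2[usable])).fit()
            for pred in usable:
                rows.append(
                    {"metric": metric, "predictor": pred,
                     "coef": float(step2.params[pred]), "se": float(step2.bse[pred]),
                     "p": float(step2.pvalues[pred]), "n": len(sub)}
                )
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    for pred, idx in out.groupby("predictor").groups.items():
        out.loc[idx, "p_adj"] = benjamini_hochberg(out.loc[idx, "p"])
    return out


# ---------------------------------------------------------------------------
# somatic distance profile
# ---------------------------------------------------------------------------

def somatic_distance_profile(
    pair_records: pd.DataFrame,
    metric: str,
    bin_width: float = 100.0,
    distance_col: str = "somatic_distance",
) -> pd.DataFrame:
    """Mean +- s.e. of a similarity metric by 100-um somatic-distance bin,
    separately for connected pairs and unconnected pairs sharing the same
    presynaptic population. Empty bins are reported with n = 0."""
    d = pair_records[distance_col].to_numpy(float)
    edges = np.arange(0, np.ceil(d.max() / bin_width) * bin_width + bin_width, bin_width)
    connected = pair_records["n_syn"] >= 1
    rows = []
    for k in range(len(edges) - 1):
        in_bin = (d >= edges[k]) & (d < edges[k + 1])
        for label, mask in (("connected", connected), ("unconnected", ~connected)):
            vals = pair_records.loc[in_bin & mask, metric].dropna()
            rows.append(
                {
                    "bin_left": edges[k], "bin_right": edges[k + 1],
                    "group": label, "n": len(vals),
                    "mean": vals.mean() if len(vals) else np.nan,
                    "se": vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)
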
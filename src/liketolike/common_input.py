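"""Higher-order common-input analysis.

Tests whether the postsynaptic targets of a single presynaptic neuron are
more functionally similar to each other than a purely pairwise wiring rule
predicts. The observed convergence statistic for presynaptic neuron i is the
synapse-count-weighted mean pairwise similarity among its postsynaptic
candidates,

    rho(i) = sum_{j != i} sum_{k not in (i, j)} Sim_jk N_ij N_ik
             / sum sum N_ij N_ik,

and the expected statistic rho'(i) replaces N by the mean synapse counts N'
predicted from a fitted pairwise model (one Poisson mixed model over all
pairs, all similarity metrics with projection interactions). A two-sided
Wilcoxon signed-rank test compares rho and rho' across presynaptic neurons.

Since Sim is symmetric the ordered double sum equals twice the unordered
sum; the implementation sums unordered pairs (the doubling factor cancels in
the ratio).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from liketolike.glmm import GlmmResult, fit_glmm


@dataclass
class ConvergenceScore:
    presyn_id: int
    rho_observed: float
    rho_expected: float
    n_postsyn: int
    projection: str = "all"


def _rho_from_weights(weights: np.ndarray, similarity: np.ndarray) -> float:
    """Weighted mean pairwise similarity; weights are per-candidate synapse
    counts (observed or predicted). Undefined (nan) with < 2 weighted
    candidates."""
    w = np.asarray(weights, float)
    S = np.asarray(similarity, float)
    if (w > 0).sum() < 2:
        return float("nan")
    outer = np.outer(w, w)
    np.fill_diagonal(outer, 0.0)
    ok = np.isfinite(S)
    np.fill_diagonal(ok, False)
    denom = outer[ok].sum()
    if denom <= 0:
        return float("nan")
    return float((outer[ok] * S[ok]).sum() / denom)


def rho_observed(
    synapse_counts: np.ndarray, similarity_matrix: np.ndarray
) -> float:
    """Observed convergence statistic for one presynaptic neuron.

    ``synapse_counts``: N_syn from the presyn to each candidate (length m);
    ``similarity_matrix``: (m, m) symmetric pairwise similarities among the
    candidates.
    """
    return _rho_from_weights(synapse_counts, similarity_matrix)


def rho_expected(
    predicted_counts: np.ndarray, similarity_matrix: np.ndarray
) -> float:
    """Expected convergence statistic under a pairwise rule: same double sum
    with predicted mean synapse counts N'."""
    return _rho_from_weights(predicted_counts, similarity_matrix)


def fit_pairwise_null(
    pair_records: pd.DataFrame,
    similarity_cols=("feature_similarity",),
) -> tuple[GlmmResult, np.ndarray, list]:
    """One Poisson mixed model of N_syn over all pairs.

    All supplied similarity metrics enter jointly with projection
    interactions; random intercepts group presynaptic neurons within
    projection-by-proofread strata (as in the like-to-like models). Returns
    the fit, the predicted mean count N' per row of ``pair_records`` and the
    design column names. Predictions marginalize over the random effects
    (zero random intercept), so N' depends on functional similarity and
    projection only — the pairwise rule, not presyn identity.
    """
    pairs = pair_records
    y = pairs["n_syn"].to_numpy(float)
    projections = sorted(pairs["projection"].unique())
    cols = [np.ones(len(pairs))]
    names = ["intercept"]
    sims = {c: pairs[c].to_numpy(float) for c in similarity_cols}
    for c in similarity_cols:
        cols.append(sims[c])
        names.append(c)
    for proj in projections[1:]:
        d = (pairs["projection"] == proj).to_numpy(float)
        cols.append(d)
        names.append(f"proj[{proj}]")
        for c in similarity_cols:
            cols.append(d * sims[c])
            names.append(f"{c}:proj[{proj}]")
    X = np.column_stack(cols)
    proofread = pairs["proofread"] if "proofread" in pairs else "all"
    groups = (
        pairs["projection"].astype(str)
        + "|"
        + pd.Series(proofread, index=pairs.index).astype(str)
        + "|"
        + pairs["pre_id"].astype(str)
    ).to_numpy()
    result = fit_glmm(y, X, groups=groups, family="poisson", exog_names=names)
    predicted = result.predict(X)  # random effects marginalized out
    return result, predicted, names


def convergence_scores(
    pair_records: pd.DataFrame,
    predicted_counts: np.ndarray,
    similarity_matrix: np.ndarray,
    unit_index: dict,
    min_postsyn: int = 2,
) -> list[ConvergenceScore]:
    """rho and rho' for every presynaptic neuron in the pair table.

    ``similarity_matrix`` is indexed via ``unit_index`` (unit id -> row).
    Candidates j, k run over all filtered co-registered units appearing as
    postsynaptic candidates of the presyn (the predicted count is defined
    for every pair, which is what lets rho' differ from rho).
    """
    pairs = pair_records.copy()
    pairs["_nprime"] = np.asarray(predicted_counts, float)
    out = []
    for pre, sub in pairs.groupby("pre_id"):
        cand = sub["post_id"].to_numpy()
        rows = np.array([unit_index[c] for c in cand])
        S = similarity_matrix[np.ix_(rows, rows)]
        n_obs = sub["n_syn"].to_numpy(float)
        n_prime = sub["_nprime"].to_numpy(float)
        if (n_obs > 0).sum() < min_postsyn:
            continue
        out.append(
            ConvergenceScore(
                presyn_id=pre,
                rho_observed=_rho_from_weights(n_obs, S),
                rho_expected=_rho_from_weights(n_prime, S),
                n_postsyn=int((n_obs > 0).sum()),
            )
        )
    return out


def compare_convergence(scores: list[ConvergenceScore], min_presyn: int = 5) -> dict:
    """Two-sided Wilcoxon signed-rank test of rho vs rho' across presyn.

    Returns a report dict with the statistic, p-value, effect direction and
    sample size; ``testable`` is False with too few defined scores or
    all-zero differences.
    """
    obs = np.array([s.rho_observed for s in scores])
    exp = np.array([s.rho_expected for s in scores])
    ok = np.isfinite(obs) & np.isfinite(exp)
    obs, exp = obs[ok], exp[ok]
    report = {
        "n_presyn": int(ok.sum()),
        "median_diff": float(np.median(obs - exp)) if ok.sum() else np.nan,
        "direction": "observed>expected" if ok.sum() and np.median(obs - exp) > 0
        else "observed<=expected",
        "testable": False,
        "statistic": np.nan,
        "p": np.nan,
    }
    if ok.sum() < min_presyn:
        return report
    diff = obs - exp
    if np.allclose(diff, 0):
        return report
    res = stats.wilcoxon(obs, exp, alternative="two-sided")
    report.update(testable=True, statistic=float(res.statistic), p=float(res.pvalue))
    return report


def common_input_analysis(
    pair_records: pd.DataFrame,
    feature_weights: np.ndarray,
    unit_ids: np.ndarray,
    similarity_cols=("feature_similarity",),
    min_postsyn: int = 2,
) -> dict:
    """End-to-end common-input test on a pair table.

    Builds the candidate similarity matrix (feature cosine), fits the
    pairwise null, computes rho / rho' per presyn and runs the Wilcoxon
    comparison. Returns {"scores": ..., "report": ..., "null_model": ...}.
    """
    W = np.asarray(feature_weights, float)
    norms = np.linalg.norm(W, axis=1, keepdims=True)
    Wn = W / np.where(norms == 0, 1, norms)
    S = Wn @ Wn.T
    unit_index = {int(u): k for k, u in enumerate(unit_ids)}
    null_model, predicted, _ = fit_pairwise_null(pair_records, similarity_cols)
    scores = convergence_scores(
        pair_records, predicted, S, unit_index, min_postsyn=min_postsyn
    )
    report = compare_convergence(scores)
    return {"scores": scores, "report": report, "null_model": null_model}
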
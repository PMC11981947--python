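"""Per-unit and pairwise functional metrics.

Reliability gates (CC_max, CC_abs), signal correlation over 500-ms bins,
feature-weight cosine similarity, receptive-field-centre distance in visual
angle, and orientation tuning (gOSI, OSI, von Mises mixture fit).

Undefined metrics (zero variance, negative radicand, all-zero tuning) are
returned as ``nan``, never as zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import pearsonr

#: unit-inclusion thresholds
CC_MAX_THRESHOLD = 0.4
CC_ABS_THRESHOLD = 0.2
GOSI_THRESHOLD = 0.25

#: monitor geometry: eye-to-monitor distance (cm), monitor centred on and
#: normal to the eye axis; physical half-extent of the monitor plane in cm
#: used to convert normalized [-1, 1] readout coordinates.
EYE_DISTANCE_CM = 15.0
DEFAULT_MONITOR_HALF_WIDTH_CM = 28.0
DEFAULT_MONITOR_HALF_HEIGHT_CM = 16.0

N_DIRECTIONS = 16
DIRECTION_GRID_DEG = np.arange(N_DIRECTIONS) * (360.0 / N_DIRECTIONS)


@dataclass
class ReliabilityScores:
    unit_id: int
    cc_max: float
    cc_abs: float

    @property
    def passes(self) -> bool:
        return (
            np.isfinite(self.cc_max)
            and np.isfinite(self.cc_abs)
            and self.cc_max > CC_MAX_THRESHOLD
            and self.cc_abs > CC_ABS_THRESHOLD
        )


def cc_max(repeat_block: np.ndarray) -> float:
    """Upper bound of attainable model-data correlation from repeated trials.

    ``repeat_block`` is (n_repeats, n_bins). With trial-mean trace ybar and
    per-bin across-trial variance Var(y),

        CC_max = sqrt((N Var(ybar) - mean Var(y)) / ((N - 1) Var(ybar)))

    Returns nan when the radicand is negative (reliability indistinguishable
    from zero) or the trial mean is constant.
    """
    y = np.asarray(repeat_block, float)
    if y.ndim != 2 or y.shape[0] < 2:
        raise ValueError("need a (n_repeats >= 2, n_bins) block")
    n = y.shape[0]
    var_mean = y.mean(axis=0).var(ddof=1)
    mean_var = y.var(axis=1, ddof=1).mean()
    if var_mean <= 0:
        return float("nan")
    radicand = (n * var_mean - mean_var) / ((n - 1) * var_mean)
    if radicand < 0:
        return float("nan")
    return float(np.sqrt(radicand))


def cc_abs(predicted: np.ndarray, observed_trial_mean: np.ndarray) -> float:
    """Pearson correlation between trial-averaged prediction and observation."""
    x = np.asarray(predicted, float)
    y = np.asarray(observed_trial_mean, float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length traces with >= 3 bins")
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(pearsonr(x, y).statistic)


def signal_correlation(resp_i: np.ndarray, resp_j: np.ndarray) -> float:
    """Pearson correlation of two units' binned responses, trials concatenated."""
    x = np.asarray(resp_i, float).ravel()
    y = np.asarray(resp_j, float).ravel()
    if x.shape != y.shape:
        raise ValueError("responses must share binning")
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(pearsonr(x, y).statistic)


def signal_correlation_matrix(responses: np.ndarray) -> np.ndarray:
    """Pairwise signal correlations for a (units, bins) response matrix.

    Constant units get nan rows/columns.
    """
    r = np.asarray(responses, float)
    sd = r.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(r)
    c[sd == 0, :] = np.nan
    c[:, sd == 0] = np.nan
    return c


def feature_similarity(w_i: np.ndarray, w_j: np.ndarray) -> float:
    """Cosine similarity of two readout feature-weight vectors."""
    a = np.asarray(w_i, float).ravel()
    b = np.asarray(w_j, float).ravel()
    if a.shape != b.shape:
        raise ValueError("feature vectors must share length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return float("nan")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def _monitor_vector(loc, half_width_cm, half_height_cm) -> np.ndarray:
    """Eye-to-point vector for a normalized [-1,1]^2 monitor location."""
    loc = np.asarray(loc, float)
    return np.array(
        [loc[0] * half_width_cm, loc[1] * half_height_cm, EYE_DISTANCE_CM]
    )


def rf_centre_distance(
    loc_i,
    loc_j,
    half_width_cm: float = DEFAULT_MONITOR_HALF_WIDTH_CM,
    half_height_cm: float = DEFAULT_MONITOR_HALF_HEIGHT_CM,
) -> float:
    """Visual angle (degrees) between two readout locations.

    Locations are normalized monitor coordinates in [-1, 1]^2; the monitor is
    centred on, 15 cm from, and normal to the eye. Locations outside the
    monitor extent are still computed (the geometry extends the plane).
    """
    v1 = _monitor_vector(loc_i, half_width_cm, half_height_cm)
    v2 = _monitor_vector(loc_j, half_width_cm, half_height_cm)
    cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def gosi(R: np.ndarray, directions_deg: np.ndarray = DIRECTION_GRID_DEG) -> float:
    """Global orientation selectivity index: |sum R e^{2i theta}| / sum R.

    The doubled angle maps opposite directions onto the same orientation;
    gOSI is 0 for a flat curve and 1 for a single responsive direction.
    """
    R = np.asarray(R, float)
    if np.any(R < 0):
        raise ValueError("tuning responses must be non-negative")
    total = R.sum()
    if total == 0:
        return float("nan")
    theta = np.radians(np.asarray(directions_deg, float))
    return float(np.abs(np.sum(R * np.exp(2j * theta))) / total)


def _nearest_direction_indices(target_deg: float, directions_deg: np.ndarray):
    d = np.abs((directions_deg - target_deg + 180.0) % 360.0 - 180.0)
    return int(np.argmin(d))


def osi(
    R: np.ndarray,
    preferred_orientation_deg: float | None = None,
    directions_deg: np.ndarray = DIRECTION_GRID_DEG,
) -> float:
    """(R_po - R_ortho) / (R_po + R_ortho) from the measured tuning curve.

    R_po averages the curve at the two directions nearest the preferred
    orientation and its opposite; R_ortho likewise at +-90 degrees. When no
    preferred orientation is supplied, the argmax direction defines it.
    """
    R = np.asarray(R, float)
    if R.sum() == 0:
        return float("nan")
    if preferred_orientation_deg is None:
        preferred_orientation_deg = float(directions_deg[int(np.argmax(R))]) % 180.0
    po = preferred_orientation_deg
    r_po = np.mean(
        [
            R[_nearest_direction_indices(po, directions_deg)],
            R[_nearest_direction_indices(po + 180.0, directions_deg)],
        ]
    )
    r_ortho = np.mean(
        [
            R[_nearest_direction_indices(po + 90.0, directions_deg)],
            R[_nearest_direction_indices(po + 270.0, directions_deg)],
        ]
    )
    if r_po + r_ortho == 0:
        return float("nan")
    return float((r_po - r_ortho) / (r_po + r_ortho))


def von_mises_mixture(theta_rad: np.ndarray, mu, kappa, alpha, beta, gamma) -> np.ndarray:
    """Two von Mises bumps pi apart sharing dispersion kappa, plus offset."""
    return (
        alpha * np.exp(kappa * np.cos(theta_rad - mu))
        + beta * np.exp(kappa * np.cos(theta_rad - mu + np.pi))
        + gamma
    )


@dataclass
class DirectionTuningFit:
    mu_deg: float
    kappa: float
    alpha: float
    beta: float
    gamma: float
    residual: float  # sum of squared residuals
    preferred_orientation_deg: float
    reliable: bool  # False for flat curves (kappa -> 0)


def fit_direction_tuning(
    R: np.ndarray,
    directions_deg: np.ndarray = DIRECTION_GRID_DEG,
    n_mu_starts: int = 8,
) -> DirectionTuningFit:
    """Least-squares fit of the two-bump von Mises mixture to a tuning curve.

    The sum of squared residuals sum_theta (f(theta) - R_theta)^2 is
    minimized from ``n_mu_starts`` equispaced mu starts (kappa start 1); the
    best residual wins, ties broken toward smaller kappa. The preferred
    orientation is mu modulo 180 degrees. A near-flat fitted curve
    (kappa ~ 0 or vanishing amplitudes) is flagged unreliable.
    """
    R = np.asarray(R, float)
    theta = np.radians(np.asarray(directions_deg, float))

    def residuals(p):
        mu, log_kappa, alpha, beta, gamma = p
        kappa = np.exp(np.clip(log_kappa, -12.0, 6.0))  # keeps exp(kappa) finite
        return von_mises_mixture(theta, mu, kappa, alpha, beta, gamma) - R

    best = None
    amp0 = max(R.max() - R.min(), 1e-6)
    for mu0 in np.linspace(0, 2 * np.pi, n_mu_starts, endpoint=False):
        p0 = [mu0, 0.0, amp0 / np.e, amp0 / (2 * np.e), R.min()]
        sol = least_squares(residuals, p0, method="lm", max_nfev=5000)
        cost = 2 * sol.cost  # SSR
        kappa = np.exp(np.clip(sol.x[1], -12.0, 6.0))
        key = (round(cost, 10), kappa)
        if best is None or key < best[0]:
            best = (key, sol)
    sol = best[1]
    mu, log_kappa, alpha, beta, gamma = sol.x
    kappa = float(np.exp(np.clip(log_kappa, -12.0, 6.0)))
    # canonicalize: keep the larger bump as alpha at direction mu
    if beta > alpha:
        alpha, beta = beta, alpha
        mu = mu + np.pi
    mu_deg = float(np.degrees(mu) % 360.0)
    ssr = float(2 * sol.cost)
    flat_ssr = float(np.sum((R - R.mean()) ** 2))
    reliable = kappa > 1e-3 and abs(alpha) * (np.exp(kappa) - 1) > 1e-6 and ssr < flat_ssr
    return DirectionTuningFit(
        mu_deg=mu_deg,
        kappa=kappa,
        alpha=float(alpha),
        beta=float(beta),
        gamma=float(gamma),
        residual=ssr,
        preferred_orientation_deg=mu_deg % 180.0,
        reliable=reliable,
    )


def delta_preferred_orientation(theta1_deg: float, theta2_deg: float) -> float:
    """Acute angular difference between two orientations, in [0, 90] degrees."""
    d = abs(theta1_deg - theta2_deg) % 180.0
    return float(min(d, 180.0 - d))
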
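"""Cohort-level statistics: copula simulation, normality testing and the
normative prediction ellipse.

The cohort table has one row per subject with columns ``age``, ``ess``
(Epworth Sleepiness Scale, 0-24), ``entropy`` (bits), ``det_pct``
(determinism, %) and ``pct_change`` (mean pupil percent change). A Gaussian
copula preserving the Pearson dependence structure and the empirical margins
expands the observed cohort; bivariate normality of the (entropy,
determinism) margin is screened with the Doornik-Hansen omnibus test; the
95% prediction ellipse in the (ENT, DET/100) plane provides the normative
region, and its geometry yields determinism reference intervals per entropy
bin.

The ellipse axis lengths are ``a = 2 * sqrt(lambda * (n-1) * p *
F_crit(p, n-p) / (n-p))`` with ``lambda`` the covariance eigenvalues in
descending order and ``F_crit`` the upper 1-alpha quantile of F(p, n-p);
the plotted semiaxes are ``a/2``. The orientation is the angle of the
leading eigenvector, folded into [0, pi).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateInputError, DomainError

COHORT_COLUMNS = ["age", "ess", "entropy", "det_pct", "pct_change"]
INTEGER_COLUMNS = ["age", "ess"]


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Check the cohort table schema and basic invariants."""
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise DomainError(f"cohort table missing columns {missing}")
    df = cohort[COHORT_COLUMNS].copy()
    if len(df) < 3:
        raise DegenerateInputError("cohort needs at least 3 rows")
    if df.isna().any().any():
        raise DomainError("cohort table has missing cells")
    return df


def correlation_matrix(cohort: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of the five cohort features."""
    df = validate_cohort(cohort)
    if (df.std(ddof=0) == 0).any():
        bad = df.columns[df.std(ddof=0) == 0].tolist()
        raise DegenerateInputError(f"zero-variance column(s): {bad}")
    return df.corr(method="pearson")


def nearest_psd(corr: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Clip negative eigenvalues and renormalize to unit diagonal."""
    lam, vec = np.linalg.eigh(corr)
    if lam.min() >= eps:
        return corr
    lam = np.maximum(lam, eps)
    fixed = vec @ np.diag(lam) @ vec.T
    d = np.sqrt(np.diag(fixed))
    return fixed / np.outer(d, d)


def empirical_inverse_cdf(observed: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Inverse empirical CDF with linear interpolation between order stats."""
    return np.quantile(np.asarray(observed, float), u, method="linear")


def gaussian_copula_sample(cohort: pd.DataFrame, n_out: int,
                           seed: int | np.random.Generator | None = None
                           ) -> pd.DataFrame:
    """Simulate a cohort preserving margins and Pearson dependence.

    Latent multivariate-normal draws with the cohort's Pearson correlation
    are pushed through the standard normal CDF and then each margin's
    empirical inverse CDF; ``age`` and ``ess`` are rounded to integers.
    """
    df = validate_cohort(cohort)
    corr = correlation_matrix(df).to_numpy()
    corr = nearest_psd(corr)
    rng = np.random.default_rng(seed)
    z = rng.multivariate_normal(np.zeros(len(COHORT_COLUMNS)), corr,
                                size=n_out, method="eigh")
    u = stats.norm.cdf(z)
    out = {}
    for j, col in enumerate(COHORT_COLUMNS):
        vals = empirical_inverse_cdf(df[col].to_numpy(), u[:, j])
        if col in INTEGER_COLUMNS:
            vals = np.round(vals).astype(int)
        out[col] = vals
    return pd.DataFrame(out)


def _dagostino_skew_z(rb1: float, n: int) -> float:
    """D'Agostino (1970) transform of sqrt(b1) to approximate normality."""
    beta = (3.0 * (n ** 2 + 27 * n - 70) * (n + 1) * (n + 3)
            / ((n - 2) * (n + 5) * (n + 7) * (n + 9)))
    w2 = -1.0 + np.sqrt(2.0 * (beta - 1.0))
    delta = 1.0 / np.sqrt(np.log(np.sqrt(w2)))
    y = rb1 * np.sqrt((w2 - 1.0) * (n + 1) * (n + 3) / (12.0 * (n - 2)))
    return float(delta * np.log(y + np.sqrt(y * y + 1.0)))


def _gamma_kurt_z(b2: float, rb1: float, n: int) -> float:
    """Gamma/Wilson-Hilferty transform of b2 conditional on skewness."""
    d = (n - 3) * (n + 1) * (n ** 2 + 15 * n - 4)
    a = (n - 2) * (n + 5) * (n + 7) * (n ** 2 + 27 * n - 70) / (6.0 * d)
    c = (n - 7) * (n + 5) * (n + 7) * (n ** 2 + 2 * n - 5) / (6.0 * d)
    k = (n + 5) * (n + 7) * (n ** 3 + 37 * n ** 2 + 11 * n - 313) / (12.0 * d)
    alpha = a + rb1 ** 2 * c
    chi = max((b2 - 1.0 - rb1 ** 2) * 2.0 * k, 1e-12)
    return float((((chi / (2 * alpha)) ** (1.0 / 3.0)) - 1.0
                  + 1.0 / (9.0 * alpha)) * np.sqrt(9.0 * alpha))


def doornik_hansen(points: np.ndarray) -> tuple[float, float]:
    """Doornik-Hansen omnibus test for multivariate normality.

    The data are centered, scaled to unit variance, decorrelated with the
    symmetric inverse square root of the correlation matrix, and each
    transformed coordinate contributes squared skewness and kurtosis
    z-transforms. The statistic is chi-squared with ``2 p`` degrees of
    freedom under the null.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2:
        raise DomainError("points must be a 2-D array")
    n, p = X.shape
    if n <= 7:
        raise DegenerateInputError("need more than 7 observations")
    Xc = X - X.mean(axis=0)
    S = Xc.T @ Xc / n
    d = np.sqrt(np.diag(S))
    if np.any(d == 0):
        raise DegenerateInputError("zero-variance column")
    V = S / np.outer(d, d)
    lam, H = np.linalg.eigh(V)
    if lam.min() <= 1e-12:
        raise DegenerateInputError("singular correlation matrix")
    L = H @ np.diag(lam ** -0.5) @ H.T
    Y = (Xc / d) @ L
    E = 0.0
    for y in Y.T:
        m2 = float(np.mean(y ** 2))
        rb1 = float(np.mean(y ** 3)) / m2 ** 1.5
        b2 = float(np.mean(y ** 4)) / m2 ** 2
        E += _dagostino_skew_z(rb1, n) ** 2 + _gamma_kurt_z(b2, rb1, n) ** 2
    return float(E), float(stats.chi2.sf(E, 2 * p))


@dataclass
class PredictionEllipse:
    """A (1 - alpha) prediction ellipse in the (ENT, rescaled-DET) plane.

    ``a_x`` and ``a_y`` are the axis *lengths* of the axis formulas; the
    geometric semiaxes are ``a_x / 2`` and ``a_y / 2``.
    """

    center: tuple[float, float]
    a_x: float
    a_y: float
    theta: float
    alpha: float

    def __post_init__(self) -> None:
        if not (self.a_x >= self.a_y > 0):
            raise DomainError("require a_x >= a_y > 0")
        self.theta = float(self.theta % np.pi)

    @property
    def eccentricity(self) -> float:
        return float(np.sqrt(1.0 - (self.a_y / self.a_x) ** 2))

    @property
    def area(self) -> float:
        return float(np.pi * (self.a_x / 2) * (self.a_y / 2))

    def to_dict(self) -> dict:
        return {"center": list(self.center), "a_x": self.a_x,
                "a_y": self.a_y, "theta": self.theta, "alpha": self.alpha,
                "eccentricity": self.eccentricity, "area": self.area}


def prediction_ellipse(points: np.ndarray,
                       alpha: float = 0.05) -> PredictionEllipse:
    """Fit the (1 - alpha) prediction ellipse to bivariate points.

    The second column is expected already rescaled to order 1 (DET / 100).
    """
    X = np.asarray(points, dtype=float)
    n, p = X.shape
    if p != 2:
        raise DomainError("prediction ellipse is bivariate")
    if n <= p:
        raise DegenerateInputError("need more observations than variables")
    S = np.cov(X.T)
    lam, vec = np.linalg.eigh(S)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    if lam[1] <= 0:
        raise DegenerateInputError("degenerate covariance (zero eigenvalue)")
    fcrit = stats.f.ppf(1.0 - alpha, p, n - p)
    scale = (n - 1) * p * fcrit / (n - p)
    a_x = 2.0 * np.sqrt(lam[0] * scale)
    a_y = 2.0 * np.sqrt(lam[1] * scale)
    theta = float(np.arctan2(vec[1, 0], vec[0, 0]))
    center = (float(X[:, 0].mean()), float(X[:, 1].mean()))
    return PredictionEllipse(center=center, a_x=float(a_x), a_y=float(a_y),
                             theta=theta, alpha=alpha)


def ellipse_contour(ellipse: PredictionEllipse,
                    t_grid: np.ndarray | None = None) -> np.ndarray:
    """Parametric contour points (closed curve over t in [0, 2 pi))."""
    if t_grid is None:
        t_grid = np.linspace(0.0, 2.0 * np.pi, 361)
    t = np.asarray(t_grid, dtype=float)
    sx, sy = ellipse.a_x / 2.0, ellipse.a_y / 2.0
    ct, st = np.cos(t), np.sin(t)
    cth, sth = np.cos(ellipse.theta), np.sin(ellipse.theta)
    px = ellipse.center[0] + sx * ct * cth - sy * st * sth
    py = ellipse.center[1] + sx * ct * sth + sy * st * cth
    return np.column_stack([px, py])


def contains(ellipse: PredictionEllipse, point: np.ndarray,
             tol: float = 1e-10) -> np.ndarray | bool:
    """Membership predicate; boundary points count as inside."""
    pt = np.atleast_2d(np.asarray(point, dtype=float))
    u = pt[:, 0] - ellipse.center[0]
    v = pt[:, 1] - ellipse.center[1]
    cth, sth = np.cos(ellipse.theta), np.sin(ellipse.theta)
    ur = u * cth + v * sth
    vr = -u * sth + v * cth
    q = (ur / (ellipse.a_x / 2.0)) ** 2 + (vr / (ellipse.a_y / 2.0)) ** 2
    inside = q <= 1.0 + tol
    return bool(inside[0]) if np.asarray(point).ndim == 1 else inside


def normative_intervals(ellipse: PredictionEllipse,
                        ent_bin_width: float = 0.05,
                        det_scale: float = 100.0,
                        n_contour: int = 200_001) -> pd.DataFrame:
    """Determinism reference interval per entropy bin.

    For every entropy bin (aligned to multiples of the bin width) that
    intersects the ellipse's x-extent, the minimum and maximum of the
    ellipse's y-section over that bin are reported, rescaled by
    ``det_scale`` and rounded to integers.
    """
    if ent_bin_width <= 0:
        raise DomainError("ent_bin_width must be positive")
    contour = ellipse_contour(
        ellipse, np.linspace(0.0, 2.0 * np.pi, n_contour))
    x, y = contour[:, 0], contour[:, 1]
    x_lo, x_hi = x.min(), x.max()
    first = np.floor(x_lo / ent_bin_width)
    last = np.ceil(x_hi / ent_bin_width)
    rows = []
    for k in range(int(first), int(last)):
        lo, hi = k * ent_bin_width, (k + 1) * ent_bin_width
        mask = (x >= lo) & (x <= hi)
        if not mask.any():
            continue
        rows.append({
            "ent_lo": round(lo, 10), "ent_hi": round(hi, 10),
            "det_min": int(round(det_scale * y[mask].min())),
            "det_max": int(round(det_scale * y[mask].max())),
        })
    return pd.DataFrame(rows)
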
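"""Statsmodels-style front end for the cohort-level analysis.

``NormativePupilModel`` wraps an observed cohort feature table; ``fit``
runs the population chain — Gaussian-copula expansion (or a user-supplied
simulated table), Doornik-Hansen bivariate normality screening, the 95%
prediction ellipse in the (ENT, DET/100) plane, determinism reference
intervals per entropy bin, and the two-cluster comparison battery — and
returns a :class:`NormativePupilResults` carrying every estimate plus a
``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cluster_inference as ci
from . import population_stats as ps


class NormativePupilModel:
    """Normative ENT-DET model of the dark-adapted pupil cohort.

    Parameters
    ----------
    cohort : DataFrame
        Observed feature table with columns ``age, ess, entropy, det_pct,
        pct_change``.
    det_scale : float
        Divisor mapping determinism (%) onto the ellipse's y axis.
    """

    def __init__(self, cohort: pd.DataFrame, det_scale: float = 100.0):
        self.cohort = ps.validate_cohort(cohort)
        self.det_scale = det_scale

    @classmethod
    def from_csv(cls, path, **kwargs) -> "NormativePupilModel":
        return cls(pd.read_csv(path), **kwargs)

    def simulate(self, n: int = 100, seed=None) -> pd.DataFrame:
        """Draw a Gaussian-copula cohort preserving margins and dependence."""
        return ps.gaussian_copula_sample(self.cohort, n, seed)

    def fit(self, alpha: float = 0.05, n_sim: int = 100, seed=None,
            simulated: pd.DataFrame | None = None,
            ent_bin_width: float = 0.05,
            n_init: int = 20) -> "NormativePupilResults":
        """Run the full population analysis.

        ``simulated`` substitutes a pre-computed simulated cohort for a
        fresh copula draw, decoupling the downstream geometry from
        simulation randomness.
        """
        rng = np.random.default_rng(seed)
        corr = ps.correlation_matrix(self.cohort)
        sim = (ps.validate_cohort(simulated) if simulated is not None
               else self.simulate(n_sim, rng))
        pts = np.column_stack([sim["entropy"],
                               sim["det_pct"] / self.det_scale])
        dh = ps.doornik_hansen(pts)
        ellipse = ps.prediction_ellipse(pts, alpha=alpha)
        intervals = ps.normative_intervals(ellipse, ent_bin_width,
                                           self.det_scale)
        clusters = ci.compare_clusters(sim, ellipse, self.det_scale,
                                       seed=rng, n_init=n_init)
        return NormativePupilResults(
            model=self, correlation=corr, simulated=sim, dh=dh,
            ellipse=ellipse, normative=intervals, clusters=clusters,
            alpha=alpha, seed=seed)


@dataclass
class NormativePupilResults:
    """Estimates, diagnostics and inference from a fitted cohort model."""

    model: NormativePupilModel
    correlation: pd.DataFrame
    simulated: pd.DataFrame
    dh: tuple[float, float]
    ellipse: ps.PredictionEllipse
    normative: pd.DataFrame
    clusters: ci.ClusterComparison
    alpha: float
    seed: object = None

    def summary(self) -> str:
        e = self.ellipse
        c = self.clusters
        lines = [
            "Normative pupil ENT-DET model",
            "=" * 46,
            f"observed cohort n = {len(self.model.cohort)}, "
            f"simulated n = {len(self.simulated)}",
            f"Pearson r(ENT, DET) observed = "
            f"{self.correlation.loc['entropy', 'det_pct']:.3f}",
            f"Doornik-Hansen: stat = {self.dh[0]:.3f}, p = {self.dh[1]:.3f}",
            "",
            f"{100 * (1 - self.alpha):.0f}% prediction ellipse "
            "(ENT, DET/100):",
            f"  center        ({e.center[0]:.3f}, {e.center[1]:.3f})",
            f"  axes (a_x,a_y) {e.a_x:.3f}, {e.a_y:.3f}",
            f"  angle          {e.theta:.3f} rad "
            f"({np.degrees(e.theta):.1f} deg)",
            f"  eccentricity   {e.eccentricity:.3f}   area {e.area:.3f}",
            "",
            f"clusters inside ellipse: n = {len(c.labels)} "
            f"({int((c.labels == 0).sum())} / {int((c.labels == 1).sum())})",
            f"  ENT centroids  {c.centroids[0][0]:.3f} / "
            f"{c.centroids[1][0]:.3f}",
            f"  Box's M        {c.box_m[0]:.2f} (p = {c.box_m[1]:.3f})",
            f"  Hotelling T2   {c.hotelling[0]:.1f} "
            f"(p = {c.hotelling[1]:.2g})",
        ]
        for var, (u, pv) in c.u_tests.items():
            lines.append(f"  U ({var:<10s}) {u:.1f} (p = {pv:.3f})")
        return "\n".join(lines)

    def to_report(self) -> dict:
        """Machine-readable report embedding the resolved configuration."""
        return {
            "config": {"alpha": self.alpha, "seed": self.seed,
                       "det_scale": self.model.det_scale,
                       "n_sim": len(self.simulated)},
            "correlation": self.correlation.to_dict(),
            "doornik_hansen": {"statistic": self.dh[0], "p": self.dh[1]},
            "ellipse": self.ellipse.to_dict(),
            "normative_intervals": self.normative.to_dict(orient="records"),
            "clusters": self.clusters.to_dict(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_report(), fh, indent=2, default=float)

    def plot(self, ax=None):
        """Scatter of simulated points, cluster labels and ellipse contour."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pts = np.column_stack([self.simulated["entropy"],
                               self.simulated["det_pct"]
                               / self.model.det_scale])
        contour = ps.ellipse_contour(self.ellipse)
        inside = self.clusters.interior_index
        lab = self.clusters.labels
        ax.plot(contour[:, 0], contour[:, 1], "k-", lw=1)
        outside = np.setdiff1d(np.arange(len(pts)), inside)
        ax.plot(pts[outside, 0], pts[outside, 1], "x", color="grey",
                label="outside")
        for j, marker in ((0, "o"), (1, "s")):
            sel = inside[lab == j]
            ax.plot(pts[sel, 0], pts[sel, 1], marker,
                    label=f"cluster {j + 1}")
        ax.plot(*zip(*self.clusters.centroids), "+k", ms=14, mew=3)
        ax.set_xlabel("entropy (bits)")
        ax.set_ylabel("determinism (rescaled)")
        ax.legend(loc="best", fontsize="small")
        return ax
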
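"""Sloan neutral community model: fit, stochasticity R², and occupancy partition.

Under Sloan's continuous approximation of neutral assembly, a taxon with
metacommunity relative abundance ``p`` is detected (local abundance above
the detection limit ``d``) in a fraction of hosts equal to the survival
function of a Beta distribution:

    freq_pred(p) = 1 − BetaCDF(d; Nm·p, Nm·(1 − p))

where ``N`` is the local community size (reads per sample after leveling)
and ``m`` the migration rate — the probability that a local death is
replaced by an immigrant rather than by local reproduction. The composite
parameter ``Nm`` is estimated by bounded nonlinear least squares of the
predicted against the observed occurrence frequencies over taxa, and the
goodness of fit R² = 1 − SS_res/SS_tot is read as the share of community
assembly attributable to stochastic processes (1 − R² deterministic). Taxa
outside a 95% band around the prediction (Wilson score intervals with n =
number of samples) are candidates for deterministic selection: above the
band, selected for; below, selected against.

Usage follows the model/results convention::

    result = NeutralCommunityModel.from_table(table).fit()
    result.m, result.r2, result.partition_proportions()
    print(result.summary())
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import beta as beta_dist
from statsmodels.stats.proportion import proportion_confint

from .tables import OtuTable

logger = logging.getLogger("gutassembly")


class NcmFitError(RuntimeError):
    """The least-squares fit did not converge; carries the SSE profile."""

    def __init__(self, message: str, profile: pd.DataFrame | None = None):
        super().__init__(message)
        self.profile = profile


class NeutralCommunityModel:
    """Sloan neutral model for an abundance–occupancy relation.

    Parameters
    ----------
    p : array
        Mean relative abundance of each taxon across samples (the
        metacommunity abundance estimate).
    freq_obs : array
        Fraction of samples in which each taxon is detected.
    N : int
        Local community size (reads per sample).
    n_samples : int
        Number of samples behind each observed frequency (sets the width
        of the 95% band).
    detection_limit : float, optional
        Default 1/N, the smallest detectable relative abundance.
    """

    def __init__(self, p, freq_obs, N, n_samples, detection_limit=None, ids=None):
        p = np.asarray(p, dtype=float)
        freq_obs = np.asarray(freq_obs, dtype=float)
        keep = freq_obs > 0  # undetected taxa carry no occupancy information
        self.p = p[keep]
        self.freq_obs = freq_obs[keep]
        self.ids = (np.asarray(ids)[keep] if ids is not None
                    else np.array([f"taxon{i}" for i in np.flatnonzero(keep)]))
        self.N = int(N)
        self.n_samples = int(n_samples)
        self.d = float(detection_limit) if detection_limit is not None else 1.0 / self.N
        if self.p.size < 2 or np.ptp(self.p) == 0:
            raise ValueError("degenerate abundance vector: need >= 2 distinct p values")
        if np.any((self.p <= 0) | (self.p >= 1)):
            raise ValueError("mean relative abundances must lie strictly in (0, 1)")
        if self.p.size < 50 or self.n_samples < 10:
            logger.warning(
                "NCM fit on %d taxa / %d samples; results may be unstable below "
                "50 taxa and 10 samples", self.p.size, self.n_samples,
            )

    @classmethod
    def from_table(cls, table: OtuTable, detection_limit=None) -> "NeutralCommunityModel":
        """Build the model from an OTU table (uniform depth expected).

        With non-uniform depth, N falls back to the mean depth with a
        warning.
        """
        depths = table.depth.to_numpy()
        if np.ptp(depths) > 0:
            logger.warning("non-uniform depth; using mean depth as N")
            N = int(round(depths.mean()))
        else:
            N = int(depths[0])
        rel = table.relative_abundance()
        p = rel.mean(axis=1).to_numpy()
        freq_obs = (table.counts.to_numpy() > 0).mean(axis=1)
        return cls(p, freq_obs, N=N, n_samples=table.n_samples,
                   detection_limit=detection_limit, ids=table.taxon_ids.to_numpy())

    def predict(self, nm: float, p=None) -> np.ndarray:
        """Predicted occurrence frequency at composite parameter ``nm``."""
        p = self.p if p is None else np.asarray(p, dtype=float)
        return beta_dist.sf(self.d, nm * p, nm * (1.0 - p))

    def sse(self, nm: float) -> float:
        return float(((self.predict(nm) - self.freq_obs) ** 2).sum())

    def sse_profile(self, n_points: int = 60) -> pd.DataFrame:
        grid = np.geomspace(1e-2, 10.0 * self.N, n_points)
        return pd.DataFrame({"Nm": grid, "sse": [self.sse(v) for v in grid]})

    def fit(self, n_starts: int = 3, bounds=None) -> "NcmResults":
        """Estimate Nm by bounded nonlinear least squares (multi-start).

        ``n_starts`` log-spaced initial values guard against the flat SSE
        profiles occupancy data can produce. Raises :class:`NcmFitError`
        with the SSE profile attached if no start converges.
        """
        lo, hi = bounds if bounds is not None else (1e-3, 10.0 * self.N)
        starts = np.geomspace(max(lo * 10, 1e-2), hi / 10.0, n_starts)
        best = None
        for x0 in starts:
            try:
                res = optimize.least_squares(
                    lambda v: self.predict(v[0]) - self.freq_obs,
                    x0=[x0], bounds=([lo], [hi]),
                )
            except Exception:
                continue
            if res.success and (best is None or res.cost < best.cost):
                best = res
        if best is None:
            raise NcmFitError("NCM least squares did not converge",
                              profile=self.sse_profile())
        nm = float(best.x[0])
        return self._results(nm)

    def _results(self, nm: float) -> "NcmResults":
        freq_pred = self.predict(nm)
        ss_res = float(((self.freq_obs - freq_pred) ** 2).sum())
        ss_tot = float(((self.freq_obs - self.freq_obs.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        ci_low, ci_high = proportion_confint(
            freq_pred * self.n_samples, self.n_samples, alpha=0.05, method="wilson"
        )
        partition = np.where(self.freq_obs > ci_high, "above",
                             np.where(self.freq_obs < ci_low, "below", "within"))
        records = pd.DataFrame({
            "p": self.p,
            "log10_p": np.log10(self.p),
            "freq_obs": self.freq_obs,
            "freq_pred": freq_pred,
            "ci_low": ci_low,
            "ci_high": ci_high,
            "partition": partition,
        }, index=pd.Index(self.ids, name="otu_id"))
        return NcmResults(model=self, N=self.N, d=self.d, nm=nm,
                          m=nm / self.N, r2=r2, records=records)


@dataclass
class NcmResults:
    """Fitted Sloan neutral model: estimates, band partition, summary."""

    model: NeutralCommunityModel
    N: int
    d: float
    nm: float
    m: float
    r2: float
    records: pd.DataFrame

    def partition_proportions(self) -> tuple[float, float, float]:
        """(above, within, below) fractions of taxa relative to the 95% band."""
        counts = self.records["partition"].value_counts()
        n = len(self.records)
        return tuple(float(counts.get(k, 0)) / n for k in ("above", "within", "below"))

    def to_dict(self) -> dict:
        above, within, below = self.partition_proportions()
        return {
            "N": self.N, "detection_limit": self.d, "Nm": self.nm,
            "m": self.m, "r2": self.r2, "n_taxa": int(len(self.records)),
            "n_samples": self.model.n_samples,
            "proportion_above": above, "proportion_within": within,
            "proportion_below": below,
        }

    def summary(self) -> str:
        above, within, below = self.partition_proportions()
        lines = [
            "Sloan neutral community model",
            "=" * 46,
            f"{'taxa (detected)':<28}{len(self.records):>18d}",
            f"{'samples':<28}{self.model.n_samples:>18d}",
            f"{'community size N':<28}{self.N:>18d}",
            f"{'detection limit d':<28}{self.d:>18.3e}",
            f"{'Nm (composite)':<28}{self.nm:>18.3f}",
            f"{'migration rate m':<28}{self.m:>18.4f}",
            f"{'stochasticity R2':<28}{self.r2:>18.4f}",
            f"{'above 95% band':<28}{above:>17.1%}",
            f"{'within 95% band':<28}{within:>17.1%}",
            f"{'below 95% band':<28}{below:>17.1%}",
            "=" * 46,
        ]
        return "\n".join(lines)


def fit_ncm(table: OtuTable, detection_limit=None) -> NcmResults:
    """Fit the neutral model to one OTU table."""
    return NeutralCommunityModel.from_table(table, detection_limit).fit()


def fit_ncm_by_site(table: OtuTable, detection_limit=None) -> dict:
    """Fit the neutral model separately within each site."""
    out = {}
    for site in sorted(table.meta["site"].unique()):
        cols = table.meta.index[table.meta["site"] == site]
        sub = OtuTable(table.counts[cols], table.lineages, table.meta.loc[cols])
        out[site] = fit_ncm(sub, detection_limit)
    return out
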
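"""miRNA quantification, CLIP-enrichment mixture fit and cpc calibration.

Counts of reads annotating to mature miRNAs are normalised to reads per
million miRNA-annotated reads (RPM).  The CLIP-engaged subset of the pool
shows up as the upper component of a clearly bimodal distribution of mean
log10 RPM across CLIP libraries; a two-component Gaussian mixture fit by EM
separates it.  Absolute copies per cell (cpc) are calibrated by ordinary
least squares of log cpc on log RPM through a small set of experimentally
quantified anchor miRNAs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.mixture import GaussianMixture

from .errors import ConfigurationError, EstimationError

logger = logging.getLogger(__name__)

#: quantitative-northern-blot copies-per-cell demo anchors
DEMO_CPC_ANCHORS = pd.DataFrame({
    "mirna_id": ["miR-184-3p", "miR-14-3p", "miR-7-5p"],
    "cpc": [36600.0, 10150.0, 620.0],
})

#: ranked truncations of the enriched set used downstream
TOP_K_PRESETS = {"high_confidence": 30, "comprehensive": 59}


def compute_rpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Reads-per-million normalisation per library (column).

    ``counts`` is miRNAs x libraries; every column is divided by its total
    and multiplied by 1e6, so each library's RPM sums to one million.
    """
    if counts.size == 0:
        raise ConfigurationError("empty count table")
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ConfigurationError(f"libraries with zero total counts: {bad}")
    return counts / totals * 1e6


@dataclass(frozen=True)
class MixtureFit:
    """Two-component Gaussian mixture over mean log10 RPM values."""

    means: tuple[float, float]       # sorted ascending
    sds: tuple[float, float]
    weights: tuple[float, float]
    posterior_upper: pd.Series       # P(upper component | value)
    enriched: list[str]              # posterior > 0.5 for the upper component
    ranked: list[str]                # all ids, by value descending

    def top(self, k: int | str) -> list[str]:
        """Top-k truncation; accepts preset names from TOP_K_PRESETS."""
        if isinstance(k, str):
            k = TOP_K_PRESETS[k]
        return self.ranked[:k]


def fit_enrichment_mixture(
    values: pd.Series,
    seed: int = 0,
    max_iter: int = 500,
) -> MixtureFit:
    """EM fit of a 1-D two-component Gaussian mixture.

    ``values`` maps miRNA id to mean log10 RPM across CLIP libraries.
    Initialisation is k-means with 10 restarts; components are reported
    sorted by mean, and the enriched set is everything with posterior > 0.5
    for the higher-mean component.
    """
    values = values.dropna()
    if len(values) < 10:
        raise ConfigurationError(
            f"mixture fit needs >= 10 miRNAs, got {len(values)}"
        )
    x = values.to_numpy(dtype=float).reshape(-1, 1)
    if np.ptp(x) == 0:
        raise EstimationError("all values identical; mixture is degenerate")
    gm = GaussianMixture(
        n_components=2, n_init=10, init_params="kmeans",
        max_iter=max_iter, random_state=int(seed),
    ).fit(x)
    if not gm.converged_:
        raise EstimationError(
            f"EM did not converge in {max_iter} iterations "
            f"(lower bound {gm.lower_bound_:.4f})"
        )
    order = np.argsort(gm.means_.ravel())
    means = tuple(float(gm.means_.ravel()[i]) for i in order)
    sds = tuple(float(np.sqrt(gm.covariances_.ravel()[i])) for i in order)
    weights = tuple(float(gm.weights_[i]) for i in order)
    post = gm.predict_proba(x)[:, order[1]]
    posterior = pd.Series(post, index=values.index)
    enriched = sorted(values.index[post > 0.5])
    ranked = list(values.sort_values(ascending=False).index)
    return MixtureFit(means, sds, weights, posterior, enriched, ranked)


@dataclass(frozen=True)
class CpcModel:
    """log-log linear calibration from RPM to copies per cell."""

    slope: float
    intercept: float      # log10 scale
    r_squared: float
    resid_se: float       # residual standard error on the log10-cpc scale
    n_anchors: int


def fit_cpc_model(anchors: pd.DataFrame) -> CpcModel:
    """OLS of log10(cpc) on log10(RPM) through the anchor miRNAs.

    ``anchors`` needs columns ``cpc`` and ``rpm``; both must be positive
    and at least three anchors are required.
    """
    for col in ("cpc", "rpm"):
        if col not in anchors.columns:
            raise ConfigurationError(f"anchors need a {col!r} column")
    if len(anchors) < 3:
        raise ConfigurationError("cpc fit needs >= 3 anchors")
    if (anchors[["cpc", "rpm"]] <= 0).any().any():
        raise ConfigurationError("anchor cpc and RPM values must be positive")
    x = np.log10(anchors["rpm"].to_numpy(dtype=float))
    y = np.log10(anchors["cpc"].to_numpy(dtype=float))
    res = sm.OLS(y, sm.add_constant(x)).fit()
    dof = max(len(anchors) - 2, 1)
    return CpcModel(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        resid_se=float(np.sqrt(res.ssr / dof)),
        n_anchors=len(anchors),
    )


def predict_cpc(model: CpcModel, rpm) -> np.ndarray | float:
    """Back-transformed cpc prediction; monotone increasing in RPM."""
    rpm_arr = np.asarray(rpm, dtype=float)
    if (rpm_arr <= 0).any():
        raise ConfigurationError("RPM must be positive for cpc prediction")
    out = 10.0 ** (model.intercept + model.slope * np.log10(rpm_arr))
    return float(out) if np.isscalar(rpm) else out
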
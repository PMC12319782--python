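"""Shape-sensitivity slopes across object-scrambling conditions.

For each source q and scrambling level i the condition contribution is the
ratio ``beta_{q,i} = beta_q^{Si} / beta_q^{rest}``, with the resting-state
covariance model used as the common normalizer (a model refit per condition
would absorb the very condition effect the slope measures).  The slope
``alpha_q`` of ``beta_{q,i}`` over the ordinal scrambling axis
(S256, S64, S16, S4, S1) -> (1..5) is estimated by ordinary least squares;
positive alpha means stronger responses to more intact shapes (shape
sensitivity), negative alpha means edge sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .headmodel import Leadfield, estimate_covariances
from .silencemap import contribution_ratio, source_contribution
from .spectral import EEGRecording

__all__ = [
    "SCRAMBLING_ORDER",
    "ConditionContributions",
    "SlopeMap",
    "DeltaMap",
    "condition_contributions",
    "fit_shape_slope",
    "delta_map",
]

#: most -> least scrambled; the regression abscissa is 1..5 in this order.
SCRAMBLING_ORDER = ("S256", "S64", "S16", "S4", "S1")


@dataclass
class ConditionContributions:
    """Sources x 5 matrix of rest-normalized contributions, fixed column order."""

    beta: np.ndarray
    band: str
    subject: Optional[str] = None

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.ndim != 2 or self.beta.shape[1] != len(SCRAMBLING_ORDER):
            raise ValueError("beta must be sources x 5 (S256..S1)")
        if not np.isfinite(self.beta).all() or (self.beta < 0).any():
            raise ValueError("contributions must be finite and nonnegative")


@dataclass
class SlopeMap:
    """Per-source shape-sensitivity slope and intercept."""

    alpha: np.ndarray
    intercept: np.ndarray
    band: str
    subject: Optional[str] = None

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.intercept = np.asarray(self.intercept, dtype=float)
        if not (np.isfinite(self.alpha).all() and np.isfinite(self.intercept).all()):
            raise ValueError("slopes must be finite")


@dataclass
class DeltaMap:
    """Per-source slope difference, case minus control."""

    delta: np.ndarray
    case: str
    control: str
    band: str


def condition_contributions(
    recordings: Mapping[str, EEGRecording],
    lf: Leadfield,
    band: Optional[str] = None,
    noise_frac: float = 0.25,
) -> ConditionContributions:
    """Rest-normalized contribution measures for all five scrambling levels.

    ``recordings`` maps condition name to a band-filtered recording; all five
    scrambling conditions plus "rest" must be present and share the band.
    The resting covariance model normalizes every condition, so the ratio
    reduces to the noise-corrected matched-filter power relative to rest.
    """
    for cond in ("rest",) + SCRAMBLING_ORDER:
        if cond not in recordings:
            raise ValueError(f"missing condition {cond!r}")
    rest = recordings["rest"]
    band = band or rest.band
    for cond, rec in recordings.items():
        if rec.band != band:
            raise ValueError(f"condition {cond!r} is in band {rec.band}, expected {band}")

    cov_rest = estimate_covariances(rest, lf, noise_frac=noise_frac)
    beta_rest = source_contribution(rest, lf, cov_rest)
    cols = []
    for cond in SCRAMBLING_ORDER:
        rec = recordings[cond]
        cov_i = estimate_covariances(rec, lf, noise_frac=noise_frac)
        # rest-fitted source model as the common normalizer; condition-specific
        # scalp and noise covariances in the numerator
        cov_mixed = type(cov_rest)(C_x=cov_i.C_x, C_z=cov_i.C_z,
                                   s_var=cov_rest.s_var, selec=cov_rest.selec)
        beta_i = source_contribution(rec, lf, cov_mixed)
        cols.append(contribution_ratio(beta_i, beta_rest).beta)
    return ConditionContributions(beta=np.stack(cols, axis=1), band=band,
                                  subject=rest.subject)


def fit_shape_slope(cc: ConditionContributions) -> SlopeMap:
    """Ordinary least squares of beta_{q,i} on the ordinal axis x = 1..5.

    The slope equals the closed form sum((x-xbar)(y-ybar)) / sum((x-xbar)^2)
    per source; exact for noiseless linear inputs.
    """
    B = cc.beta
    if not np.isfinite(B).all():
        raise ValueError("non-finite contributions")
    x = np.arange(1, 6, dtype=float)
    xc = x - x.mean()
    denom = float(xc @ xc)
    ybar = B.mean(axis=1)
    alpha = (B - ybar[:, None]) @ xc / denom
    intercept = ybar - alpha * x.mean()
    return SlopeMap(alpha=alpha, intercept=intercept, band=cc.band, subject=cc.subject)


def delta_map(case: SlopeMap, control: SlopeMap) -> DeltaMap:
    """Elementwise slope difference; negative values mean reduction in the case."""
    if case.band != control.band:
        raise ValueError(f"band mismatch: {case.band} vs {control.band}")
    if case.alpha.shape != control.alpha.shape:
        raise ValueError("slope maps live on different source spaces")
    return DeltaMap(delta=case.alpha - control.alpha,
                    case=case.subject or "case",
                    control=control.subject or "control",
                    band=case.band)
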
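"""The three-part biallelic-MUTYH tumor-signature classifier.

A tumor is called positive for biallelic MUTYH inactivation when
(1) the combined SBS18+SBS36 exposure exceeds 51% (strict),
(2) the cosine reconstruction error is below 39% (strict), and
(3) the panel-adjusted somatic mutation count is at least 9 (inclusive).
Counts from panels of other sizes are scaled down to the 1.34 Mb reference
panel by the ratio of capture sizes before the count test.

The SBS18/36 threshold can be re-derived from a labelled training cohort as
the smallest signature level at which the estimated posterior probability of
biallelic carriership reaches a target likelihood (default 95%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin


@dataclass(frozen=True)
class ClassifierParams:
    """Decision thresholds of the optimized classifier.

    sig_threshold_pct : SBS18+SBS36 percentage above which (strictly) the
        signature test passes.
    error_threshold_pct : reconstruction-error percentage below which
        (strictly) the error test passes.
    min_snv : minimum adjusted somatic mutation count (inclusive).
    reference_panel_mb : capture size (Mb) on which the thresholds were set.
    target_likelihood : posterior level used when deriving the signature
        threshold from training data.
    """

    sig_threshold_pct: float = 51.0
    error_threshold_pct: float = 39.0
    min_snv: float = 9.0
    reference_panel_mb: float = 1.34
    target_likelihood: float = 0.95

    def __post_init__(self) -> None:
        if min(self.sig_threshold_pct, self.error_threshold_pct, self.min_snv) <= 0:
            raise ValueError("classifier thresholds must be positive")
        if self.reference_panel_mb <= 0:
            raise ValueError("reference_panel_mb must be positive")
        if not (0 < self.target_likelihood < 1):
            raise ValueError("target_likelihood must be in (0,1)")


@dataclass(frozen=True)
class MutyhCall:
    """Classifier verdict with its three component tests and echoed inputs."""

    positive: bool
    sig_pass: bool
    error_pass: bool
    count_pass: bool
    adjusted_snv: float
    sbs18_36_pct: float
    error_pct: float
    n_snv: float
    panel_mb: float

    def __post_init__(self) -> None:
        if self.positive != (self.sig_pass and self.error_pass and self.count_pass):
            raise ValueError("positive must equal the conjunction of the three component tests")


def adjust_count(n_snv: float, panel_mb: float, params: ClassifierParams | None = None) -> float:
    """Scale a mutation count down to the reference panel size.

    ``n_snv * reference_panel_mb / panel_mb`` — the identity when the tumor
    was sequenced on the reference panel itself.
    """
    params = params or ClassifierParams()
    if panel_mb <= 0:
        raise ValueError("panel_mb must be positive")
    return n_snv * params.reference_panel_mb / panel_mb


def classify(
    sbs18_36_pct: float,
    error_pct: float,
    n_snv: float,
    panel_mb: float | None = None,
    params: ClassifierParams | None = None,
) -> MutyhCall:
    """Apply the three-part rule; inequality strictness follows the printed rule."""
    params = params or ClassifierParams()
    if panel_mb is None:
        panel_mb = params.reference_panel_mb
    if not (0 <= sbs18_36_pct <= 100) or not (0 <= error_pct <= 100):
        raise ValueError("percentages must lie in [0, 100]")
    if n_snv < 0:
        raise ValueError("n_snv must be non-negative")
    adj = adjust_count(n_snv, panel_mb, params)
    sig_pass = sbs18_36_pct > params.sig_threshold_pct
    error_pass = error_pct < params.error_threshold_pct
    count_pass = adj >= params.min_snv
    return MutyhCall(
        positive=sig_pass and error_pass and count_pass,
        sig_pass=sig_pass,
        error_pass=error_pass,
        count_pass=count_pass,
        adjusted_snv=adj,
        sbs18_36_pct=sbs18_36_pct,
        error_pct=error_pct,
        n_snv=n_snv,
        panel_mb=panel_mb,
    )


class ThresholdDerivationError(RuntimeError):
    """No signature level reaches the target posterior on this training set."""


def derive_threshold(
    training: Sequence[tuple[float, bool]],
    params: ClassifierParams | None = None,
    grid_step: float = 0.5,
) -> float:
    """Derive the SBS18/36 threshold from labelled training TMS values.

    The posterior P(biallelic | sbs18_36 = t) is estimated from
    class-conditional Gaussian kernel density estimates (Silverman bandwidth)
    with equal class priors, on a percentage grid of the given step.  Returns
    the smallest grid value at which the posterior reaches
    ``params.target_likelihood`` and stays there for all larger values.
    """
    params = params or ClassifierParams()
    vals = np.array([v for v, _ in training], dtype=float)
    labels = np.array([bool(l) for _, l in training])
    pos, neg = vals[labels], vals[~labels]
    if len(pos) < 2 or len(neg) < 10:
        raise ValueError("need at least 2 biallelic and 10 non-biallelic training tumors")
    kde_pos = stats.gaussian_kde(pos)
    kde_neg = stats.gaussian_kde(neg)
    grid = np.arange(0.0, 100.0 + grid_step / 2, grid_step)
    dp = kde_pos(grid)
    dn = kde_neg(grid)
    posterior = dp / (dp + dn)
    ok = posterior >= params.target_likelihood
    if not ok[-1]:
        raise ThresholdDerivationError(
            "posterior never stays at the target likelihood; enlarge the training "
            "set or lower target_likelihood"
        )
    # smallest t with posterior >= target from t upward
    below = np.nonzero(~ok)[0]
    idx = below[-1] + 1 if len(below) else 0
    if idx >= len(grid):
        raise ThresholdDerivationError("target likelihood not reached on the grid")
    return float(grid[idx])


class MutyhTmsClassifier(ClassifierMixin, BaseEstimator):
    """Sklearn-style wrapper around the three-part rule.

    ``fit(X, y)`` with 1-column X (SBS18/36 %) and boolean y re-derives the
    signature threshold from the training cohort; ``fit(None)`` freezes the
    constructor thresholds.  ``predict`` consumes rows of
    ``[sbs18_36_pct, error_pct, n_snv, panel_mb]`` (panel column optional,
    defaulting to the reference panel) and returns boolean calls.

    Attributes
    ----------
    sig_threshold_pct_ : float
        Active SBS18/36 threshold after fitting.
    params_ : ClassifierParams
        Fully resolved decision parameters.
    """

    def __init__(
        self,
        sig_threshold_pct: float = 51.0,
        error_threshold_pct: float = 39.0,
        min_snv: float = 9.0,
        reference_panel_mb: float = 1.34,
        target_likelihood: float = 0.95,
    ):
        self.sig_threshold_pct = sig_threshold_pct
        self.error_threshold_pct = error_threshold_pct
        self.min_snv = min_snv
        self.reference_panel_mb = reference_panel_mb
        self.target_likelihood = target_likelihood

    def fit(self, X=None, y=None):
        base = ClassifierParams(
            sig_threshold_pct=self.sig_threshold_pct,
            error_threshold_pct=self.error_threshold_pct,
            min_snv=self.min_snv,
            reference_panel_mb=self.reference_panel_mb,
            target_likelihood=self.target_likelihood,
        )
        if X is not None and y is not None:
            vals = np.asarray(X, dtype=float).reshape(-1)
            y = np.asarray(y).astype(bool)
            thr = derive_threshold(list(zip(vals.tolist(), y.tolist())), base)
            self.sig_threshold_pct_ = thr
        else:
            self.sig_threshold_pct_ = base.sig_threshold_pct
        self.params_ = ClassifierParams(
            sig_threshold_pct=self.sig_threshold_pct_,
            error_threshold_pct=base.error_threshold_pct,
            min_snv=base.min_snv,
            reference_panel_mb=base.reference_panel_mb,
            target_likelihood=base.target_likelihood,
        )
        self.classes_ = np.array([False, True])
        return self

    def _rows(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] == 3:
            panel = np.full((X.shape[0], 1), self.params_.reference_panel_mb)
            X = np.hstack([X, panel])
        if X.shape[1] != 4:
            raise ValueError("expected columns [sbs18_36_pct, error_pct, n_snv, panel_mb]")
        return X

    def predict_calls(self, X) -> list[MutyhCall]:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "params_")
        return [classify(r[0], r[1], r[2], r[3], self.params_) for r in self._rows(X)]

    def predict(self, X) -> np.ndarray:
        return np.array([c.positive for c in self.predict_calls(X)])
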
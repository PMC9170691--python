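"""Signature exposure refitting by cosine-distance minimization.

Given a tumor's 96-class context spectrum and a fixed signature catalog, find
non-negative exposures on the probability simplex whose catalog combination
best reconstructs the spectrum, where "best" means minimum cosine distance
(the reconstruction error).  The optimizer is scipy's basin-hopping simulated
annealing in unconstrained softmax coordinates with a Nelder–Mead polish; a
dense simplex grid search is provided as an independent oracle for small
bases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator, TransformerMixin

from .catalog import BER_SIGNATURES, SignatureCatalog
from .spectrum import ContextSpectrum


def cosine_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 - cos(a, b) for non-negative vectors; scale-invariant in each argument."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("cosine_distance requires non-negative vectors")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine distance is undefined for a zero vector")
    return float(1.0 - (a @ b) / (na * nb))


def reconstruct(exposures: Mapping[str, float] | np.ndarray, catalog: SignatureCatalog) -> np.ndarray:
    """Predicted 96-class probability vector ``catalog . exposures``."""
    if isinstance(exposures, Mapping):
        e = np.array([exposures.get(n, 0.0) for n in catalog.names], dtype=float)
    else:
        e = np.asarray(exposures, dtype=float)
    if e.shape != (len(catalog),):
        raise ValueError("exposure vector length must match catalog width")
    if (e < 0).any() or abs(e.sum() - 1.0) > 1e-6:
        raise ValueError("exposures must lie on the probability simplex")
    return catalog.matrix @ e


@dataclass(frozen=True)
class ExposureSolution:
    """Refitted signature exposures for one tumor.

    ``exposures`` sum to 1; ``error`` is the cosine distance between the
    observed spectrum and the catalog prediction; ``sbs18_36`` is the combined
    SBS18+SBS36 exposure as a percentage (0 when neither is in the basis).
    """

    exposures: dict[str, float]
    error: float
    n_snv: int

    def __post_init__(self) -> None:
        total = sum(self.exposures.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"exposures sum to {total}, not 1")
        if not (0.0 <= self.error <= 1.0 + 1e-12):
            raise ValueError(f"error {self.error} outside [0,1]")

    @property
    def sbs18_36(self) -> float:
        return 100.0 * sum(self.exposures.get(s, 0.0) for s in BER_SIGNATURES)

    def vector(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self.exposures.get(n, 0.0) for n in names], dtype=float)


@dataclass(frozen=True)
class RefitConfig:
    """Basin-hopping settings; every knob of the optimizer is fixed here.

    ``n_hops`` Metropolis restarts at temperature ``temperature``, each
    proposal a Gaussian perturbation (``step_sigma``) in softmax coordinates
    followed by a Nelder–Mead polish.  ``exposure_floor`` zeroes trace
    exposures below estimation precision at panel mutation counts.
    """

    n_hops: int = 50
    step_sigma: float = 0.1
    temperature: float = 1.0
    exposure_floor: float = 1e-4
    seed: int = 42


def _softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max()
    e = np.exp(z)
    return e / e.sum()


def refit(
    spectrum: ContextSpectrum | np.ndarray,
    catalog: SignatureCatalog,
    config: RefitConfig | None = None,
) -> ExposureSolution:
    """Estimate simplex exposures minimizing cosine reconstruction error.

    Deterministic for a fixed ``config.seed``.  The returned error never
    exceeds that of the best single-signature solution (a final guard
    replaces the annealed solution with the best one-hot if annealing lost).
    """
    config = config or RefitConfig()
    counts = spectrum.counts if isinstance(spectrum, ContextSpectrum) else np.asarray(spectrum, float)
    n_snv = int(round(float(np.sum(counts))))
    if n_snv < 1:
        raise ValueError("refit requires at least one somatic SNV")
    M = catalog.matrix
    k = len(catalog)

    s = counts / np.linalg.norm(counts)

    def objective(x: np.ndarray) -> float:
        w = _softmax(x)
        pred = M @ w
        return 1.0 - float(s @ pred) / float(np.linalg.norm(pred))

    if k == 1:
        w = np.ones(1)
    else:
        rng = np.random.default_rng(config.seed)

        def take_step(x):
            return x + rng.normal(0.0, config.step_sigma, size=x.shape)

        res = optimize.basinhopping(
            objective,
            x0=np.zeros(k),  # uniform simplex point
            niter=config.n_hops,
            T=config.temperature,
            take_step=take_step,
            minimizer_kwargs={"method": "Nelder-Mead", "options": {"xatol": 1e-4, "fatol": 1e-7}},
            seed=np.random.RandomState(config.seed),
        )
        w = _softmax(res.x)

    # floor trace exposures and renormalize
    w = np.where(w < config.exposure_floor, 0.0, w)
    w = w / w.sum()
    err = cosine_distance(counts, M @ w)

    # guard: never worse than the best single signature
    one_hot_errs = [cosine_distance(counts, M[:, j]) for j in range(k)]
    j_best = int(np.argmin(one_hot_errs))
    if one_hot_errs[j_best] < err:
        w = np.zeros(k)
        w[j_best] = 1.0
        err = one_hot_errs[j_best]

    return ExposureSolution(dict(zip(catalog.names, w.tolist())), float(err), n_snv)


def grid_refit(
    spectrum: ContextSpectrum | np.ndarray,
    catalog: SignatureCatalog,
    step: float = 0.01,
) -> ExposureSolution:
    """Dense simplex grid-search refit — the independent oracle.

    Enumerates every exposure vector on the simplex lattice with the given
    step (practical for ≤3 signatures) and returns the minimum-cosine-distance
    point.  Shares nothing with :func:`refit` beyond the objective definition.
    """
    counts = spectrum.counts if isinstance(spectrum, ContextSpectrum) else np.asarray(spectrum, float)
    n_snv = int(round(float(np.sum(counts))))
    M = catalog.matrix
    k = len(catalog)
    n_steps = int(round(1.0 / step))
    if k > 3:
        raise ValueError("grid oracle is intended for bases of at most 3 signatures")

    if k == 1:
        grid = np.array([[1.0]])
    elif k == 2:
        i = np.arange(n_steps + 1)
        grid = np.column_stack([i, n_steps - i]) / n_steps
    else:
        pts = []
        for i in range(n_steps + 1):
            for j in range(n_steps + 1 - i):
                pts.append((i, j, n_steps - i - j))
        grid = np.asarray(pts, dtype=float) / n_steps

    preds = grid @ M.T  # (n_points, 96)
    s = counts / np.linalg.norm(counts)
    sims = (preds @ s) / np.linalg.norm(preds, axis=1)
    best = int(np.argmax(sims))
    w = grid[best]
    return ExposureSolution(dict(zip(catalog.names, w.tolist())), float(1.0 - sims[best]), n_snv)


class SignatureRefitter(TransformerMixin, BaseEstimator):
    """Transformer mapping context spectra to signature exposures.

    Analogous to :class:`sklearn.decomposition.SparseCoder`: the fixed basis
    (the signature catalog) is a constructor parameter and ``fit`` is a
    validation no-op, so the estimator composes with sklearn pipelines.

    Parameters
    ----------
    catalog : SignatureCatalog
        Refit basis.
    n_hops, step_sigma, temperature, exposure_floor, random_state
        Basin-hopping settings (see :class:`RefitConfig`).

    Attributes
    ----------
    signature_names_ : list of str
        Column order of the transformed output.
    errors_ : ndarray of shape (n_tumors,)
        Cosine reconstruction error per tumor from the last ``transform``.
    """

    def __init__(
        self,
        catalog: SignatureCatalog,
        n_hops: int = 50,
        step_sigma: float = 0.1,
        temperature: float = 1.0,
        exposure_floor: float = 1e-4,
        random_state: int = 42,
    ):
        self.catalog = catalog
        self.n_hops = n_hops
        self.step_sigma = step_sigma
        self.temperature = temperature
        self.exposure_floor = exposure_floor
        self.random_state = random_state

    def _config(self) -> RefitConfig:
        return RefitConfig(
            n_hops=self.n_hops,
            step_sigma=self.step_sigma,
            temperature=self.temperature,
            exposure_floor=self.exposure_floor,
            seed=self.random_state,
        )

    def fit(self, X=None, y=None):
        if not isinstance(self.catalog, SignatureCatalog):
            raise TypeError("catalog must be a SignatureCatalog")
        self.signature_names_ = list(self.catalog.names)
        return self

    def refit_spectra(self, X) -> list[ExposureSolution]:
        """Refit each row of X (spectra or ContextSpectrum list) individually."""
        self.fit()
        cfg = self._config()
        rows: list[ExposureSolution] = []
        if isinstance(X, np.ndarray) and X.ndim == 1:
            X = X[None, :]
        for row in X:
            rows.append(refit(row, self.catalog, cfg))
        return rows

    def transform(self, X) -> np.ndarray:
        """(n_tumors, 96) counts -> (n_tumors, k) simplex exposures."""
        sols = self.refit_spectra(X)
        self.errors_ = np.array([s.error for s in sols])
        return np.vstack([s.vector(self.signature_names_) for s in sols])
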
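"""Gaussian-mixture standardization and classification of log10 DAMRatios.

Across screens the log10 DAMRatio distribution is bimodal: a left peak of
low-productive and a right peak of high-productive variants. To compare
screens we fit a Gaussian mixture and shift the scale so the left-most
component mean sits at zero. A variant is called "high" when its posterior
under the right-most component exceeds its posterior under the left-most
one (any middle component is reported but not used for the call).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

__all__ = ["MixtureFit", "fit_mixture", "standardize", "classify"]


@dataclass
class MixtureFit:
    """Fitted mixture, components sorted by mean; shift = left-most mean."""

    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    shift: float
    seed: int
    log_likelihood: float
    bic: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "shift": self.shift,
            "seed": self.seed,
            "log_likelihood": self.log_likelihood,
            "bic": self.bic,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureFit":
        return cls(
            k=d["k"],
            weights=np.asarray(d["weights"]),
            means=np.asarray(d["means"]),
            sds=np.asarray(d["sds"]),
            shift=d["shift"],
            seed=d["seed"],
            log_likelihood=d["log_likelihood"],
            bic=d.get("bic", {}),
        )


def _fit_k(x: np.ndarray, k: int, seed: int) -> GaussianMixture:
    gm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        tol=1e-6,
        max_iter=500,
        n_init=20,
        init_params="k-means++",
        reg_covar=1e-10,
        random_state=seed,
    )
    gm.fit(x)
    return gm


def fit_mixture(values, k="auto", seed: int = 0, min_n: int = 200) -> MixtureFit:
    """EM fit of a 2- or 3-component Gaussian mixture to 1-D values.

    ``k="auto"`` chooses between 2 and 3 components by BIC. The fit is
    deterministic for a given seed (20 seeded k-means++ restarts, best
    log-likelihood kept). Components with sd < 1e-4 are pruned by refitting
    with one fewer component.
    """
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} values, got {len(x)}")
    if float(np.std(x)) == 0.0:
        raise ValueError("degenerate input: zero variance")

    bic_table: dict = {}
    if k == "auto":
        # K=1 is included so unimodal (degenerate) libraries standardize to
        # their single peak instead of an artificial left half-component.
        fits = {kk: _fit_k(x, kk, seed) for kk in (1, 2, 3)}
        bic_table = {kk: float(f.bic(x)) for kk, f in fits.items()}
        k = min(bic_table, key=bic_table.get)
        gm = fits[k]
    else:
        k = int(k)
        gm = _fit_k(x, k, seed)
        bic_table = {k: float(gm.bic(x))}

    weights = gm.weights_.ravel()
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    while np.any(sds < 1e-4) and k > 1:
        warnings.warn(
            f"pruning degenerate component (sd < 1e-4); refitting with k={k - 1}"
        )
        k -= 1
        gm = _fit_k(x, k, seed)
        weights = gm.weights_.ravel()
        means = gm.means_.ravel()
        sds = np.sqrt(gm.covariances_.ravel())

    order = np.argsort(means)
    return MixtureFit(
        k=k,
        weights=weights[order],
        means=means[order],
        sds=sds[order],
        shift=float(means[order][0]),
        seed=seed,
        log_likelihood=float(gm.score(x) * len(x)),
        bic=bic_table,
    )


def standardize(values, fit: MixtureFit):
    """Shift values so the left-most mixture peak sits at zero."""
    return np.asarray(values, dtype=float) - fit.shift


def classify(values, fit: MixtureFit):
    """Label values high/low by left-most vs right-most component posterior.

    Returns ``(labels, posterior_high, middle_mass)`` where the posterior
    compares only the two extreme components and ties go to "low".
    ``middle_mass`` is the full-model responsibility of any middle
    components (zeros for k == 2).
    """
    x = np.asarray(values, dtype=float)
    dens = np.stack(
        [w * norm.pdf(x, m, s) for w, m, s in zip(fit.weights, fit.means, fit.sds)]
    )
    lo, hi = dens[0], dens[-1]
    with np.errstate(invalid="ignore"):
        posterior_high = np.where(lo + hi > 0, hi / (lo + hi), 0.5)
    labels = np.where(posterior_high > 0.5, "high", "low")
    total = dens.sum(axis=0)
    middle = dens[1:-1].sum(axis=0) if fit.k > 2 else np.zeros_like(x)
    middle_mass = np.where(total > 0, middle / np.maximum(total, 1e-300), 0.0)
    return labels, posterior_high, middle_mass
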
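"""Data log-likelihood of a candidate activity image.

Two noise readings are supported:

* ``gaussian`` — residuals ``G phi - obs`` are multivariate Gaussian with
  covariance ``CD`` (appropriate for e.g. filtered back projection);
* ``lognormal`` — residuals ``log10(G phi) - log10(obs)`` are multivariate
  Gaussian with covariance ``Ct`` in log image space (appropriate for
  OSEM-type iterative reconstructions).

For the log-normal density written as a density over the *linear* activity
variable, a Jacobian term ``-sum(ln(G phi)_i)`` appears; because it is
evaluated at the prediction it varies with ``phi`` and therefore affects the
Metropolis ratio.  ``include_jacobian=True`` (default) follows that density
literally; ``False`` gives the plain "Gaussian in log space" reading.  Both
are exposed because the two conventions genuinely differ and neither is
canonical.

The covariance factorization is computed once by the noise model and reused
for every evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import NoiseModel
from .grids import ActivityImage, DomainError, ReconstructedPET
from .psf import ConvolutionOperator

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class Likelihood:
    """Evaluate log L(phi) for a fixed observation, operator, and noise model."""

    obs: ReconstructedPET
    operator: ConvolutionOperator
    noise_model: NoiseModel
    kind: str = "lognormal"  # "lognormal" | "gaussian"
    include_jacobian: bool = True

    def __post_init__(self):
        if self.kind not in ("lognormal", "gaussian"):
            raise ValueError(f"unknown likelihood kind {self.kind!r}")
        if self.obs.grid != self.noise_model.grid:
            raise ValueError("observation and noise model grids differ")
        if self.operator.data_grid != self.obs.grid:
            raise ValueError("operator data grid does not match the observation")
        if self.kind == "lognormal" and np.any(self.obs.values <= 0):
            raise DomainError("log-normal likelihood requires a positive observation")
        self._obs_flat = self.obs.values.ravel()
        self._log_obs_flat = (
            np.log10(self._obs_flat) if self.kind == "lognormal" else None
        )
        n = self.obs.grid.n_pixels
        self._const = -0.5 * n * _LOG2PI - 0.5 * self.noise_model.logdet

    def loglik_from_prediction(self, pred_values: np.ndarray) -> float:
        """Log-likelihood given precomputed noise-free predicted values."""
        pred = pred_values.ravel()
        if self.kind == "gaussian":
            resid = pred - self._obs_flat
            y = self.noise_model.whiten(resid)
            return self._const - 0.5 * float(y @ y)
        if np.any(pred <= 0):
            raise DomainError("log-normal likelihood: non-positive predicted pixel")
        resid = np.log10(pred) - self._log_obs_flat
        y = self.noise_model.whiten(resid)
        ll = self._const - 0.5 * float(y @ y)
        if self.include_jacobian:
            ll -= float(np.sum(np.log(pred)))
        return ll

    def loglik(self, img: ActivityImage) -> float:
        """Log-likelihood of an activity image (up to a consistent constant)."""
        return self.loglik_from_prediction(self.operator.apply(img).values)

    def loglik_ratio(self, img_propose: ActivityImage, img_current: ActivityImage) -> float:
        """``loglik(propose) - loglik(current)``; all constants cancel exactly."""
        return self.loglik(img_propose) - self.loglik(img_current)


def make_likelihood(
    kind: str,
    obs: ReconstructedPET,
    operator: ConvolutionOperator,
    noise_model: NoiseModel,
    include_jacobian: bool = True,
) -> Likelihood:
    return Likelihood(obs, operator, noise_model, kind=kind, include_jacobian=include_jacobian)
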
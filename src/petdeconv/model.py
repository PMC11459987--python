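"""Model/results interface tying the pipeline together.

:class:`ProbabilisticDeconvolution` bundles an observed PET image, a
calibrated smoothing operator, a noise model, and a prior into a fit-able
model; :meth:`ProbabilisticDeconvolution.fit` runs the extended Metropolis
sampler and returns a :class:`DeconvolutionResults` carrying the chain, the
thinned posterior ensemble, and the derived maps and tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import analysis, sampler
from .calibration import NoiseModel, build_noise_model
from .grids import ImageGrid, ReconstructedPET, refine_grid
from .likelihood import Likelihood
from .psf import ConvolutionOperator, build_operator
from .priors import TrimodalTissuePrior, TruncatedBimodalPrior


class ProbabilisticDeconvolution:
    """Probabilistic (sampling-based) deconvolution of a reconstructed PET image.

    Parameters
    ----------
    observed : ReconstructedPET
        The noisy reconstructed PET image (kBq/ml, positive).
    operator : ConvolutionOperator
        Calibrated Gaussian smoothing operator mapping the model grid to the
        data grid.
    noise_model : NoiseModel
        Correlated noise model (typically built from ``observed`` itself via
        :func:`petdeconv.calibration.build_noise_model`).
    prior
        Prior object (e.g. :class:`TruncatedBimodalPrior` or
        :class:`TrimodalTissuePrior`) on the operator's model grid.
    likelihood_kind : str
        ``"lognormal"`` (default) or ``"gaussian"``.
    include_jacobian : bool
        Whether the log-normal density includes the ``-sum(ln G phi)``
        Jacobian term (see :mod:`petdeconv.likelihood`).
    """

    def __init__(
        self,
        observed: ReconstructedPET,
        operator: ConvolutionOperator,
        noise_model: NoiseModel,
        prior,
        likelihood_kind: str = "lognormal",
        include_jacobian: bool = True,
    ):
        if prior.grid != operator.model_grid:
            raise ValueError("prior grid must match the operator's model grid")
        self.observed = observed
        self.operator = operator
        self.noise_model = noise_model
        self.prior = prior
        self.likelihood = Likelihood(
            observed, operator, noise_model, kind=likelihood_kind,
            include_jacobian=include_jacobian,
        )

    @classmethod
    def from_observation(
        cls,
        observed: ReconstructedPET,
        a_mm: float,
        prior_kind: str = "bimodal",
        refinement: int = 1,
        noise_kwargs: dict | None = None,
        prior_kwargs: dict | None = None,
        **kwargs,
    ) -> "ProbabilisticDeconvolution":
        """Build a model from an observation and calibrated parameters.

        ``prior_kind`` selects ``"bimodal"`` (truncated two-level lesion
        prior) or ``"trimodal"`` (three-tissue prior).
        """
        model_grid = refine_grid(observed.grid, refinement)
        op = build_operator(a_mm, model_grid, observed.grid)
        nm = build_noise_model(observed, **(noise_kwargs or {}))
        pk = {"bimodal": TruncatedBimodalPrior, "trimodal": TrimodalTissuePrior}[prior_kind]
        prior = pk(model_grid, **(prior_kwargs or {}))
        return cls(observed, op, nm, prior, **kwargs)

    def fit(
        self,
        n_iter: int = 50_000,
        step: float = 0.15,
        seed=None,
        store_every: int = 10,
        adapt: bool = True,
        adapt_until: int | None = None,
        target_accept: float = 0.30,
    ) -> "DeconvolutionResults":
        """Sample the posterior and return results with a thinned ensemble."""
        chain = sampler.run_chain(
            self.prior,
            self.likelihood.loglik,
            n_iter=n_iter,
            step=step,
            seed=seed,
            store_every=store_every,
            adapt=adapt,
            adapt_until=adapt_until,
            target_accept=target_accept,
        )
        chain.burn_in = sampler.detect_burn_in(chain)
        ensemble = sampler.thin(chain, self.prior)
        return DeconvolutionResults(self, chain, ensemble)


@dataclass
class DeconvolutionResults:
    """Posterior sample and derived quantitative maps/tables."""

    model: ProbabilisticDeconvolution
    chain: sampler.Chain
    ensemble: sampler.PosteriorEnsemble

    # -- maps ---------------------------------------------------------------

    def posterior_mean(self) -> np.ndarray:
        return analysis.pointwise_stats(self.ensemble)[0]

    def posterior_variance(self) -> np.ndarray:
        return analysis.pointwise_stats(self.ensemble)[1]

    def exceedance_map(self, threshold: float = analysis.DEFAULT_THRESHOLD) -> np.ndarray:
        return analysis.exceedance_map(self.ensemble, threshold)

    # -- regions ------------------------------------------------------------

    def region_posterior(self, seed_pixel, threshold=analysis.DEFAULT_THRESHOLD,
                         connectivity: int = 1) -> analysis.RegionPosterior:
        return analysis.region_posterior(self.ensemble, seed_pixel, threshold, connectivity)

    def region_table(self, seed_pixels, true_areas_px=None,
                     threshold=analysis.DEFAULT_THRESHOLD, connectivity: int = 1) -> pd.DataFrame:
        return analysis.region_table(
            self.ensemble, seed_pixels, true_areas_px, threshold, connectivity
        )

    # -- diagnostics --------------------------------------------------------

    @property
    def acceptance_rate(self) -> float:
        start = self.ensemble.burn_in
        return self.chain.acceptance_rate(start)

    def summary(self) -> str:
        """Plain-text summary of the run and the posterior sample."""
        ch, ens = self.chain, self.ensemble
        mean, var = analysis.pointwise_stats(ens)
        lines = [
            "Probabilistic PET deconvolution",
            "=" * 46,
            f"{'iterations':<28}{ch.n_iter:>18,}",
            f"{'burn-in (iterations)':<28}{ens.burn_in:>18,}",
            f"{'integrated autocorr. time':<28}{ens.iact:>18.1f}",
            f"{'thinning interval':<28}{ens.thin_interval:>18,}",
            f"{'posterior realizations':<28}{ens.n_realizations:>18,}",
            f"{'acceptance rate (post-burn)':<28}{self.acceptance_rate:>18.3f}",
            f"{'likelihood':<28}{self.model.likelihood.kind:>18}",
            f"{'kernel range a (mm)':<28}{self.model.operator.a_mm:>18.2f}",
            f"{'posterior mean activity':<28}{mean.mean():>18.3f}",
            f"{'mean pointwise std':<28}{np.sqrt(np.nanmean(var)):>18.3f}",
            "=" * 46,
        ]
        return "\n".join(lines)
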
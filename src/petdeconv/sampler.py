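"""The extended Metropolis sampler.

Each iteration perturbs the current state with a prior-preserving move
(exploration) and accepts it with probability ``min(1, L(propose)/L(current))``
(exploitation).  Because the proposal kernel samples the prior by
construction, the prior density never needs to be evaluated — only the
likelihood ratio.  Acceptance is decided in log space to avoid underflow,
with the uniform draws taken from an RNG stream separate from the proposal
stream so proposal randomness and accept/reject randomness are independent.

The step size may be adapted toward a target acceptance rate during an
initial adaptation window and is frozen afterwards, so the post-adaptation
kernel is a fixed, valid MCMC kernel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .grids import ActivityImage, DomainError

logger = logging.getLogger(__name__)


@dataclass
class Chain:
    """One Markov chain: scalar traces every iteration, states every ``store_every``."""

    logliks: np.ndarray
    accepted: np.ndarray
    steps: np.ndarray
    stored_iterations: np.ndarray
    stored_states: list
    store_every: int
    adapt_until: int
    seed: object
    config: dict = field(default_factory=dict)
    burn_in: int | None = None

    @property
    def n_iter(self) -> int:
        return len(self.logliks)

    def acceptance_rate(self, start: int = 0, stop: int | None = None) -> float:
        return float(np.mean(self.accepted[start:stop]))


@dataclass
class PosteriorEnsemble:
    """Post-burn-in, thinned activity images plus their provenance."""

    images: np.ndarray  # (n_realizations, n_rows, n_cols)
    grid: object
    burn_in: int
    thin_interval: int
    iact: float
    stored_iterations: np.ndarray

    @property
    def n_realizations(self) -> int:
        return self.images.shape[0]


def tune_step(acceptance_rate: float, step: float, target: float = 0.30,
              gain: float = 0.5, bounds: tuple[float, float] = (1e-3, 1.0)) -> float:
    """Multiplicative step adjustment toward a target acceptance rate.

    The update is ``step * exp(gain * (rate - target))`` clipped to
    ``bounds``: full acceptance grows the step by a fixed factor, zero
    acceptance shrinks it.
    """
    new = step * float(np.exp(gain * (acceptance_rate - target)))
    return float(np.clip(new, *bounds))


def run_chain(
    prior,
    loglik_fn,
    n_iter: int,
    step: float = 0.1,
    seed=None,
    store_every: int = 10,
    adapt: bool = True,
    adapt_until: int | None = None,
    adapt_window: int = 50,
    target_accept: float = 0.30,
    initial_state=None,
) -> Chain:
    """Run the extended Metropolis algorithm.

    Parameters
    ----------
    prior
        Object with ``initial(rng)``, ``perturb(state, step, rng)`` and
        ``activity(state)``; iterating ``perturb`` alone must sample the prior.
    loglik_fn
        Callable mapping an :class:`ActivityImage` to a scalar log-likelihood,
        or ``None`` for exploration-only (prior sampling) mode.
    n_iter : int
        Number of iterations (>= 1).
    step : float
        Initial exploration step in (0, 1].
    store_every : int
        Stride for storing full states; scalar traces are kept every iteration.
    adapt, adapt_until, adapt_window, target_accept
        Step-size adaptation: active for the first ``adapt_until`` iterations
        (default ``n_iter // 5``), updating every ``adapt_window`` iterations,
        then frozen.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    master = np.random.default_rng(seed)
    prop_rng, acc_rng = (np.random.default_rng(s) for s in master.spawn(2))
    if adapt_until is None:
        adapt_until = n_iter // 5 if adapt else 0
    if not adapt:
        adapt_until = 0

    state = prior.initial(prop_rng) if initial_state is None else initial_state
    if loglik_fn is not None:
        ll = loglik_fn(prior.activity(state))
    else:
        ll = 0.0

    logliks = np.empty(n_iter)
    accepted = np.zeros(n_iter, dtype=bool)
    steps = np.empty(n_iter)
    stored_states: list = []
    stored_iterations: list[int] = []
    n_domain_rejects = 0

    for it in range(n_iter):
        proposal = prior.perturb(state, step, prop_rng)
        if loglik_fn is None:
            state, ll, acc = proposal, 0.0, True
        else:
            try:
                ll_prop = loglik_fn(prior.activity(proposal))
            except DomainError:
                n_domain_rejects += 1
                ll_prop = None
            if ll_prop is not None and np.log(acc_rng.random()) < ll_prop - ll:
                state, ll, acc = proposal, ll_prop, True
            else:
                acc = False
        logliks[it] = ll
        accepted[it] = acc
        steps[it] = step
        if it % store_every == 0:
            stored_states.append(state)
            stored_iterations.append(it)
        if it < adapt_until and (it + 1) % adapt_window == 0:
            rate = float(np.mean(accepted[it + 1 - adapt_window : it + 1]))
            step = tune_step(rate, step, target=target_accept)

    if n_domain_rejects:
        logger.warning("%d proposals rejected on likelihood domain errors", n_domain_rejects)
    return Chain(
        logliks=logliks,
        accepted=accepted,
        steps=steps,
        stored_iterations=np.asarray(stored_iterations),
        stored_states=stored_states,
        store_every=store_every,
        adapt_until=adapt_until,
        seed=seed,
        config={
            "n_iter": n_iter,
            "step0": float(steps[0]),
            "target_accept": target_accept,
            "store_every": store_every,
        },
    )


def detect_burn_in(chain: Chain, band_quantiles=(0.05, 0.95), min_inside: float = 0.85) -> int:
    """First iteration where the log-likelihood enters the stationary band and stays.

    The band is the ``[q05, q95]`` interval of the final half of the trace; the
    burn-in index is the first iteration that is inside the band and from
    which at least ``min_inside`` of the remaining trace stays inside.
    Returns the chain length (with a warning) if the trace never stabilizes.
    """
    trace = chain.logliks
    n = len(trace)
    if n < 100:
        raise ValueError("need at least 100 iterations to detect burn-in")
    tail = trace[n // 2 :]
    lo, hi = np.quantile(tail, band_quantiles)
    # a trace that is still strictly trending through its entire final half
    # never stabilized; equilibrium Metropolis traces move both ways
    d = np.diff(tail)
    if tail[-1] != tail[0] and (np.all(d >= 0) or np.all(d <= 0)):
        warnings.warn("log-likelihood trace never stabilized; burn-in set to chain length")
        return n
    inside = (trace >= lo) & (trace <= hi)
    # fraction of the trace inside the band from each index onward
    suffix = np.cumsum(inside[::-1])[::-1] / np.arange(n, 0, -1)
    ok = inside & (suffix >= min_inside)
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        warnings.warn("log-likelihood trace never stabilized; burn-in set to chain length")
        return n
    return int(idx[0])


def integrated_autocorrelation_time(x: np.ndarray) -> float:
    """IACT ``tau = 1/2 + sum_k rho_k`` via the initial positive sequence estimator.

    Successive pairs of autocorrelations are summed while their pair-sums stay
    positive (Geyer's initial positive sequence).  An i.i.d. sequence gives
    ``tau ~ 0.5``; an AR(1) with coefficient ``phi`` gives
    ``tau ~ (1 + phi) / (2 (1 - phi))``.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4:
        return 0.5
    x = x - x.mean()
    var = float(x @ x) / n
    if var == 0:
        return 0.5
    # FFT autocovariance
    m = sfft_next_fast_len(2 * n)
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n] / n
    rho = acov / acov[0]
    tau = 0.5
    k = 1
    while k + 1 < n:
        pair = rho[k] + rho[k + 1]
        if pair <= 0:
            break
        tau += pair
        k += 2
    return float(tau)


def sfft_next_fast_len(n: int) -> int:
    from scipy.fft import next_fast_len

    return next_fast_len(n)


def thin(chain: Chain, prior, burn_in: int | None = None) -> PosteriorEnsemble:
    """Thin the post-burn-in chain into an ensemble of near-independent images.

    The thinning interval is ``ceil(2 * tau)`` iterations, with ``tau`` the
    integrated autocorrelation time of the post-burn-in log-likelihood trace;
    stored states are then taken at least that far apart.  States stored
    before the burn-in index (or during step adaptation) are discarded.
    """
    if burn_in is None:
        burn_in = chain.burn_in if chain.burn_in is not None else detect_burn_in(chain)
    burn_in = max(int(burn_in), chain.adapt_until)
    if burn_in >= chain.n_iter:
        raise ValueError("burn-in reaches the chain length; no posterior sample")
    tau = integrated_autocorrelation_time(chain.logliks[burn_in:])
    interval = int(np.ceil(2.0 * tau))
    stride = max(1, int(np.ceil(interval / chain.store_every)))
    keep = np.flatnonzero(chain.stored_iterations >= burn_in)[::stride]
    if keep.size < 2:
        raise ValueError("fewer than 2 stored post-burn-in states; run the chain longer")
    images = np.stack([prior.activity(chain.stored_states[k]).values for k in keep])
    return PosteriorEnsemble(
        images=images,
        grid=prior.grid,
        burn_in=burn_in,
        thin_interval=interval,
        iact=tau,
        stored_iterations=chain.stored_iterations[keep],
    )
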
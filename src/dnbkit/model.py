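"""Linear stochastic gene-network model with a planted DNB module.

The generative process is a multivariate Ornstein--Uhlenbeck system

    dx = A(p) x dt + S dW,       Q = S S^T,

whose drift ``A(p) = A0 + p * B`` is pushed toward the stability boundary by
a scalar control parameter ``p`` in ``[0, 1)``.  ``A0`` is pure
self-degradation (``-I`` by default) and ``B`` concentrates both mutual
coupling and destabilization on a small planted gene module (the DNB), so
that the leading eigenvalue of ``A(p)`` equals ``-(1 - p)`` exactly: as
``p -> 1`` the module's relaxation time diverges, its stationary variance
and intra-module correlation blow up, and the system shows the early-warning
signature that DNB analysis is designed to detect.

The stationary covariance ``Sigma(p)`` solves the continuous Lyapunov
equation ``A(p) Sigma + Sigma A(p)^T + Q = 0`` and is the analytic ground
truth for every sampling routine in :mod:`dnbkit.synthetic`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .errors import InvalidConfigurationError, UnstableSystemError

__all__ = [
    "NetworkModel",
    "build_network",
    "stationary_covariance",
    "simulate_trajectory",
]

#: Default diffusion intensity: Q = NOISE_SCALE * I.
NOISE_SCALE = 1.0

#: Default within-module coupling.  The module's non-dominant directions have
#: drift eigenvalue -1 + p*(1 - intra_coupling); at 1.0 they stay neutral, so
#: every direction's stationary variance is nondecreasing in p and the total
#: fluctuation trace(Sigma(p)) rises monotonically toward the transition.
DEFAULT_INTRA_COUPLING = 1.0

#: Default control-parameter schedule (one value per stage, max = pre-disease).
DEFAULT_SCHEDULE = (0.1, 0.3, 0.5, 0.7, 0.95)


@dataclass(frozen=True)
class NetworkModel:
    """Stochastic linear network with a planted DNB block.

    Attributes
    ----------
    n_genes : int
        Dimension of the system.
    dnb_genes : ndarray of int
        Sorted indices of the planted module (nonempty strict subset).
    drift_base : ndarray, shape (n_genes, n_genes)
        Stable baseline drift ``A0``.
    coupling : ndarray, shape (n_genes, n_genes)
        Control-sensitivity matrix ``B``; the drift at control value ``p``
        is ``A0 + p * B``.
    noise_cov : ndarray, shape (n_genes, n_genes)
        Diffusion intensity ``Q`` (symmetric PSD).
    control_schedule : tuple of float
        Ordered per-stage control values, each in ``[0, 1)``.
    critical_stage : int
        Index of the schedule entry with maximal ``p`` (the planted
        pre-disease stage; earliest such index on ties).
    baseline_expression : ndarray, shape (n_genes,)
        Per-gene mean vector ``mu``.
    seed : int
        Seed used to draw ``mu`` (provenance only).
    """

    n_genes: int
    dnb_genes: np.ndarray
    drift_base: np.ndarray
    coupling: np.ndarray
    noise_cov: np.ndarray
    control_schedule: tuple[float, ...]
    critical_stage: int
    baseline_expression: np.ndarray
    seed: int = 0
    destabilize: str = field(default="block")

    def drift(self, p: float) -> np.ndarray:
        """Drift matrix ``A(p) = A0 + p * B``."""
        return self.drift_base + float(p) * self.coupling

    def leading_eigenvalue(self, p: float) -> float:
        """Largest real part over the spectrum of ``A(p)``."""
        return float(np.max(np.linalg.eigvals(self.drift(p)).real))

    @property
    def dnb_size(self) -> int:
        return int(len(self.dnb_genes))


def build_network(
    n_genes: int,
    dnb_size: int,
    intra_coupling: float = DEFAULT_INTRA_COUPLING,
    seed: int = 0,
    *,
    control_schedule: tuple[float, ...] = DEFAULT_SCHEDULE,
    noise_scale: float = NOISE_SCALE,
    destabilize: str = "block",
) -> NetworkModel:
    """Construct the default planted-module network.

    ``A0 = -I`` (unit self-degradation).  ``B`` is zero outside the DNB
    block.  Within the block it carries symmetric positive couplings of
    magnitude ``intra_coupling / dnb_size`` off the diagonal, plus a uniform
    diagonal increment chosen so that the leading eigenvalue of
    ``A(p) = A0 + p B`` is ``-(1 - p)`` exactly — i.e. the block's coupling
    matrix ``C`` is rescaled through its diagonal so that ``lambda_max(C) = 1``.

    With ``destabilize="global"`` the same total destabilization is instead
    spread uniformly over *all* genes (``B`` has the couplings on the block
    but every diagonal entry set so ``lambda_max`` stays 1); combined with
    ``intra_coupling=0`` this yields a fully exchangeable null model with no
    distinguished module, while keeping the leading eigenvalue ``-(1 - p)``.

    Parameters
    ----------
    n_genes, dnb_size : int
        System size and planted-module size, ``1 <= dnb_size < n_genes``.
    intra_coupling : float
        Total within-module coupling strength (>= 0); 0 gives a diagonal
        ``A(p)``.
    seed : int
        Seeds the draw of the baseline expression ``mu ~ N(8, 1)``
        (log2-microarray-like intensities).
    control_schedule : tuple of float
        Stage-wise control values, each in ``[0, 1)``.
    noise_scale : float
        ``Q = noise_scale * I``.
    destabilize : {"block", "global"}
        Where the destabilizing diagonal increment lives.
    """
    if not (1 <= dnb_size < n_genes):
        raise InvalidConfigurationError(
            f"dnb_size must satisfy 1 <= dnb_size < n_genes; "
            f"got dnb_size={dnb_size}, n_genes={n_genes}"
        )
    if intra_coupling < 0:
        raise InvalidConfigurationError("intra_coupling must be >= 0")
    if noise_scale < 0:
        raise InvalidConfigurationError("noise_scale must be >= 0")
    if destabilize not in ("block", "global"):
        raise InvalidConfigurationError(
            f"destabilize must be 'block' or 'global', got {destabilize!r}"
        )
    schedule = tuple(float(p) for p in control_schedule)
    if len(schedule) == 0:
        raise InvalidConfigurationError("control_schedule must be nonempty")
    if any(not (0.0 <= p < 1.0) for p in schedule):
        raise InvalidConfigurationError("control values must lie in [0, 1)")

    dnb = np.arange(dnb_size)
    off = intra_coupling / dnb_size  # pairwise coupling magnitude
    block = np.full((dnb_size, dnb_size), off)
    np.fill_diagonal(block, 0.0)
    # uniform coupling => top eigenvalue of the off-diagonal part is
    # off * (dnb_size - 1); lift the diagonal so lambda_max(C) = 1
    diag_increment = 1.0 - off * (dnb_size - 1)

    B = np.zeros((n_genes, n_genes))
    B[np.ix_(dnb, dnb)] = block
    if destabilize == "block":
        B[dnb, dnb] += diag_increment
    else:
        B[np.diag_indices(n_genes)] += diag_increment

    rng = np.random.default_rng(seed)
    mu = rng.normal(loc=8.0, scale=1.0, size=n_genes)

    model = NetworkModel(
        n_genes=n_genes,
        dnb_genes=dnb,
        drift_base=-np.eye(n_genes),
        coupling=B,
        noise_cov=noise_scale * np.eye(n_genes),
        control_schedule=schedule,
        critical_stage=int(np.argmax(schedule)),
        baseline_expression=mu,
        seed=int(seed),
        destabilize=destabilize,
    )
    return model


def stationary_covariance(
    model: NetworkModel, p: float, *, drift: np.ndarray | None = None
) -> np.ndarray:
    """Stationary covariance ``Sigma`` of the OU system at control value ``p``.

    Solves ``A(p) Sigma + Sigma A(p)^T + Q = 0`` (Bartels--Stewart via
    :func:`scipy.linalg.solve_continuous_lyapunov`) after verifying that
    every eigenvalue of ``A(p)`` has strictly negative real part.  The
    result is symmetrized to remove round-off asymmetry.

    ``drift`` overrides ``model.drift(p)`` (used by intervention
    simulation, where targeted genes get extra self-degradation).
    """
    A = model.drift(p) if drift is None else drift
    lead = float(np.max(np.linalg.eigvals(A).real))
    if lead >= 0.0:
        raise UnstableSystemError(
            f"drift has leading eigenvalue real part {lead:.3g} >= 0; "
            "no stationary distribution"
        )
    Q = model.noise_cov
    if not np.any(Q):
        return np.zeros_like(Q)
    sigma = scipy.linalg.solve_continuous_lyapunov(A, -Q)
    return 0.5 * (sigma + sigma.T)


def simulate_trajectory(
    model: NetworkModel,
    p: float,
    n_steps: int,
    dt: float = 0.01,
    seed: int = 0,
    *,
    burn_in: int = 0,
    drift: np.ndarray | None = None,
    n_chains: int = 1,
) -> np.ndarray:
    """Euler--Maruyama integration of the OU system (test oracle).

    Integrates ``n_chains`` independent trajectories in lockstep and pools
    them, returning the deviation-from-baseline samples with shape
    ``(n_steps * n_chains, n_genes)`` after discarding ``burn_in`` steps per
    chain.  Retained as an independent check on
    :func:`stationary_covariance`; production sampling draws exactly from
    the stationary law instead.
    """
    A = model.drift(p) if drift is None else drift
    rng = np.random.default_rng(seed)
    # Q = S S^T via (symmetric PSD) square root
    S = scipy.linalg.sqrtm(model.noise_cov).real
    sqdt = np.sqrt(dt)
    x = np.zeros((model.n_genes, n_chains))
    out = np.empty((n_steps, n_chains, model.n_genes))
    for i in range(burn_in + n_steps):
        x = x + dt * (A @ x) + sqdt * (S @ rng.standard_normal(x.shape))
        if i >= burn_in:
            out[i - burn_in] = x.T
    return out.reshape(n_steps * n_chains, model.n_genes)
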
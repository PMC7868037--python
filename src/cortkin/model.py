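"""Bayesian cubic regression of concentration on time, with Gelman-Rubin
convergence diagnostics.

The model is y_i ~ Normal(b0 + b1*t + b2*t^2 + b3*t^3, sigma^2) with
effectively uninformative priors: Normal(0, coef_sd^2) on each coefficient
(default sd 1e3) and Uniform(0, sigma_max) on sigma (default 1e4 ng/ml).
Sampling is a two-block Gibbs sampler run on a QR-orthogonalized design
(coefficients are reported on the raw-hours basis); the conjugate structure
makes each block an exact conditional draw, so mixing is near-iid while the
chain/thinning/burn-in contract of a generic MCMC run is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

N_COEF = 4
PARAM_NAMES = ("b0", "b1", "b2", "b3", "sigma")


@dataclass(frozen=True)
class Priors:
    """Prior scales. Defaults are wide enough to be effectively flat."""

    coef_sd: float = 1.0e3
    sigma_max: float = 1.0e4

    def __post_init__(self) -> None:
        if self.coef_sd <= 0 or self.sigma_max <= 0:
            raise ValueError("prior scales must be positive")


@dataclass(frozen=True)
class SamplerSettings:
    """MCMC run configuration.

    ``burnin_draws`` counts post-thinning draws discarded per chain (the
    thinning step precedes burn-in removal).
    """

    chains: int = 3
    iterations: int = 100_000
    thin: int = 3
    burnin_draws: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")
        if self.thin < 1 or self.iterations < 1:
            raise ValueError("iterations and thin must be >= 1")
        if self.iterations // self.thin <= self.burnin_draws:
            raise ValueError("iterations/thin must exceed burnin_draws")

    @property
    def kept_per_chain(self) -> int:
        return self.iterations // self.thin - self.burnin_draws


@dataclass
class PosteriorDraws:
    """Post-thinning, post-burn-in posterior draws grouped by chain.

    beta has shape (chains, draws_per_chain, 4); sigma (chains,
    draws_per_chain).  ``retained_mask`` is set by the constraint filter
    (None until then); ``rhat`` is computed on the unfiltered draws.
    """

    beta: np.ndarray
    sigma: np.ndarray
    rhat: dict[str, float] = field(default_factory=dict)
    retained_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.beta.ndim != 3 or self.beta.shape[2] != N_COEF:
            raise ValueError("beta must have shape (chains, draws, 4)")
        if self.sigma.shape != self.beta.shape[:2]:
            raise ValueError("sigma shape must match beta's leading dims")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma draws must be positive")

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_per_chain(self) -> int:
        return self.beta.shape[1]

    @property
    def n_total(self) -> int:
        return self.beta.shape[0] * self.beta.shape[1]

    @property
    def flat_beta(self) -> np.ndarray:
        return self.beta.reshape(-1, N_COEF)

    @property
    def flat_sigma(self) -> np.ndarray:
        return self.sigma.reshape(-1)

    @property
    def flat_retained(self) -> np.ndarray:
        if self.retained_mask is None:
            raise ValueError("retained_mask not set; run the constraint filter first")
        return self.retained_mask.reshape(-1)

    def retained_beta(self) -> np.ndarray:
        return self.flat_beta[self.flat_retained]

    def to_frame(self) -> pd.DataFrame:
        """One row per draw: chain, index, b0..b3, sigma[, retained]."""
        c, d = self.sigma.shape
        out = pd.DataFrame(
            {
                "chain": np.repeat(np.arange(c), d),
                "index": np.tile(np.arange(d), c),
                "b0": self.flat_beta[:, 0],
                "b1": self.flat_beta[:, 1],
                "b2": self.flat_beta[:, 2],
                "b3": self.flat_beta[:, 3],
                "sigma": self.flat_sigma,
            }
        )
        if self.retained_mask is not None:
            out["retained"] = self.flat_retained
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PosteriorDraws":
        chains = np.sort(frame["chain"].unique())
        frame = frame.sort_values(["chain", "index"], kind="stable")
        per = frame.groupby("chain").size()
        if per.nunique() != 1:
            raise ValueError("unequal draw counts per chain")
        d = int(per.iloc[0])
        beta = frame[["b0", "b1", "b2", "b3"]].to_numpy().reshape(len(chains), d, N_COEF)
        sigma = frame["sigma"].to_numpy().reshape(len(chains), d)
        mask = None
        if "retained" in frame.columns:
            mask = frame["retained"].to_numpy(dtype=bool).reshape(len(chains), d)
        return cls(beta=beta, sigma=sigma, retained_mask=mask)


def design_matrix(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return np.vander(t, N=N_COEF, increasing=True)


def predict_curve(coeffs: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Evaluate the cubic at each grid point.

    ``coeffs`` is either a length-4 vector (returns shape (len(grid),)) or
    an (n_draws, 4) array (returns shape (n_draws, len(grid))).
    """
    coeffs = np.asarray(coeffs, dtype=float)
    grid = np.asarray(grid, dtype=float)
    X = design_matrix(grid)
    if coeffs.ndim == 1:
        return X @ coeffs
    return coeffs @ X.T


def gelman_rubin(chains: np.ndarray) -> float:
    """Classic (split-free) potential scale reduction factor.

    ``chains`` has shape (n_chains, n_draws).  Returns
    sqrt(((n-1)/n * W + B/n) / W); degenerate zero-within-variance input
    yields exactly 1.0.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need a 2-D array with >= 2 chains")
    m, n = chains.shape
    if n < 10:
        raise ValueError("need >= 10 draws per chain")
    chain_means = chains.mean(axis=1)
    W = float(chains.var(axis=1, ddof=1).mean())
    B = float(n * chain_means.var(ddof=1))
    if W == 0.0:
        return 1.0
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W))


def rhat_all(draws: PosteriorDraws) -> dict[str, float]:
    out = {}
    for j, name in enumerate(PARAM_NAMES[:N_COEF]):
        out[name] = gelman_rubin(draws.beta[:, :, j])
    out["sigma"] = gelman_rubin(draws.sigma)
    return out


def _gibbs_chain_batch(
    Q: np.ndarray,
    R: np.ndarray,
    y: np.ndarray,
    settings: SamplerSettings,
    priors: Priors,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Run all chains in lockstep; returns kept (beta, sigma) draws.

    Works in the orthonormal basis gamma = R beta, where the Gaussian
    conditional has precision I/sigma^2 + P0 with P0 the transformed
    coefficient prior precision.
    """
    C = settings.chains
    n = y.size
    Qty = Q.T @ y
    yty = float(y @ y)

    # prior N(0, coef_sd^2 I) on beta -> N(0, coef_sd^2 R R^T) on gamma
    RRt = R @ R.T
    P0 = np.linalg.inv(RRt) / priors.coef_sd**2

    gamma_ols = Qty.copy()
    ssr_ols = max(yty - float(Qty @ Qty), 1e-12)
    sigma2_ols = ssr_ols / max(n - N_COEF, 1)

    # overdispersed chain starts around the OLS solution
    gamma = gamma_ols[None, :] + rng.normal(
        0.0, np.sqrt(sigma2_ols), size=(C, N_COEF)
    ) * rng.choice([0.5, 1.0, 2.0], size=(C, 1))
    sigma2 = sigma2_ols * np.exp(rng.normal(0.0, 1.0, size=C))

    kept = settings.kept_per_chain
    n_keep_total = settings.iterations // settings.thin
    out_gamma = np.empty((C, kept, N_COEF))
    out_sigma2 = np.empty((C, kept))

    eye = np.eye(N_COEF)
    shape = (n - 1) / 2.0
    sigma2_max = priors.sigma_max**2
    keep_i = 0
    for it in range(1, settings.iterations + 1):
        # gamma | sigma2 : batched 4x4 Gaussian conditional
        A = eye[None, :, :] / sigma2[:, None, None] + P0[None, :, :]
        L = np.linalg.cholesky(A)
        b = Qty[None, :] / sigma2[:, None]
        # mean = A^-1 b via two triangular solves
        z1 = np.linalg.solve(L, b[:, :, None])
        mean = np.linalg.solve(np.transpose(L, (0, 2, 1)), z1)[:, :, 0]
        z = rng.standard_normal((C, N_COEF))
        gamma = mean + np.linalg.solve(np.transpose(L, (0, 2, 1)), z[:, :, None])[:, :, 0]

        # sigma2 | gamma : inverse-gamma from flat-sigma prior, truncated
        ssr = yty - 2.0 * gamma @ Qty + np.einsum("cj,cj->c", gamma, gamma)
        ssr = np.maximum(ssr, 1e-300)
        tau = rng.gamma(shape, 1.0, size=C) / (ssr / 2.0)
        sigma2 = 1.0 / tau
        over = sigma2 > sigma2_max
        tries = 0
        while np.any(over) and tries < 1000:
            tau_new = rng.gamma(shape, 1.0, size=int(over.sum())) / (ssr[over] / 2.0)
            sigma2[over] = 1.0 / tau_new
            over = sigma2 > sigma2_max
            tries += 1
        if np.any(over):  # pathological data: clamp at the prior bound
            sigma2[over] = sigma2_max

        if it % settings.thin == 0:
            idx = keep_i - (n_keep_total - kept)  # index after burn-in removal
            if idx >= 0:
                out_gamma[:, idx, :] = gamma
                out_sigma2[:, idx] = sigma2
            keep_i += 1

    # back to the raw-hours basis: beta = R^-1 gamma
    flat = out_gamma.reshape(-1, N_COEF).T
    beta = solve_triangular(R, flat).T.reshape(C, kept, N_COEF)
    return beta, np.sqrt(out_sigma2)


def fit_cubic(
    data: pd.DataFrame,
    settings: SamplerSettings | None = None,
    priors: Priors | None = None,
) -> PosteriorDraws:
    """Fit the Bayesian cubic to a measurement subset.

    ``data`` needs columns time_h and cortisol_ng_ml.  Draws are
    post-thinning and post-burn-in; identical settings (including seed)
    reproduce identical draws.
    """
    settings = settings or SamplerSettings()
    priors = priors or Priors()
    t = data["time_h"].to_numpy(dtype=float)
    y = data["cortisol_ng_ml"].to_numpy(dtype=float)
    if t.size < 5:
        raise ValueError(f"need >= 5 observations to fit a cubic, got {t.size}")
    if np.unique(t).size < 4:
        raise ValueError(
            f"need >= 4 distinct times for an identifiable cubic, "
            f"got {np.unique(t).size}"
        )
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in the model subset")

    X = design_matrix(t)
    Q, R = np.linalg.qr(X)
    rng = np.random.default_rng(np.random.SeedSequence(settings.seed))
    beta, sigma = _gibbs_chain_batch(Q, R, y, settings, priors, rng)
    draws = PosteriorDraws(beta=beta, sigma=sigma)
    draws.rhat = rhat_all(draws)
    return draws


def ols_cubic(data: pd.DataFrame) -> np.ndarray:
    """Closed-form least-squares cubic coefficients (oracle for flat priors)."""
    t = data["time_h"].to_numpy(dtype=float)
    y = data["cortisol_ng_ml"].to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(design_matrix(t), y, rcond=None)
    return coef
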
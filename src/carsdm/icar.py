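"""Bernoulli-logit occupancy model with an intrinsic-CAR spatial effect.

Model, per valid raster cell i:

    Z_i ~ Bernoulli(pi_i),  logit(pi_i) = X_i beta + rho_j(i)

with weakly informative N(0, 100) priors on the regression coefficients, an
intrinsic CAR (iCAR) prior on the spatial effects rho (precision L / V_rho,
L the adjacency Laplacian; sum-to-zero constraint for identifiability) and a
uniform prior on V_rho over (0, V_max).

The sampler is a Polya-Gamma Gibbs scheme (Polson-Scott-Windle
augmentation): given latent PG variates the full conditionals of beta and
rho are Gaussian; rho is updated in one block through a banded Cholesky
factorization of its sparse precision, then re-centered to sum to zero every
sweep; V_rho has a truncated inverse-gamma conditional sampled by inverse
CDF. Everything is reproducible from the integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve_banded, cholesky_banded, solve_banded
from scipy.special import expit, gammaincc, gammainccinv

from ._polyagamma import pg_draws
from .landscape import CovariateStack, NeighborGraph, RasterGrid, build_neighbor_graph

__all__ = [
    "IcarFit",
    "build_cell_response",
    "build_neighbor_graph",
    "fit_icar_bernoulli",
    "deviance",
    "dic",
    "posterior_summary",
    "spatial_effect_map",
    "split_rhat",
]

_LOG_CLAMP = 1e-12


@dataclass
class IcarFit:
    """Retained MCMC draws (chain-major) plus run metadata."""

    beta: np.ndarray  # (n_chains, n_kept, p)
    rho: np.ndarray  # (n_chains, n_kept, n_cells)
    vrho: np.ndarray  # (n_chains, n_kept)
    deviance: np.ndarray  # (n_chains, n_kept)
    coef_names: list[str]
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_kept(self) -> int:
        return self.beta.shape[0] * self.beta.shape[1]

    # draw-major views (chains stacked)
    @property
    def beta_draws(self) -> np.ndarray:
        return self.beta.reshape(-1, self.beta.shape[-1])

    @property
    def rho_draws(self) -> np.ndarray:
        return self.rho.reshape(-1, self.rho.shape[-1])

    @property
    def vrho_draws(self) -> np.ndarray:
        return self.vrho.reshape(-1)

    @property
    def deviance_draws(self) -> np.ndarray:
        return self.deviance.reshape(-1)

    def max_rhat(self) -> float:
        vals = [split_rhat(self.beta[:, :, j]) for j in range(self.beta.shape[-1])]
        vals.append(split_rhat(self.vrho))
        return float(np.nanmax(vals))

    def min_ess(self) -> float:
        vals = [effective_sample_size(self.beta[:, :, j]) for j in range(self.beta.shape[-1])]
        vals.append(effective_sample_size(self.vrho))
        return float(np.nanmin(vals))

    def save(self, out_dir) -> None:
        """Serialize retained draws (compressed CSV tables) plus JSON meta."""
        import json
        from pathlib import Path

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        chain = np.repeat(np.arange(self.n_chains), self.beta.shape[1])
        beta = pd.DataFrame(self.beta_draws, columns=self.coef_names)
        beta.insert(0, "chain", chain)
        beta.to_csv(out_dir / "beta_draws.csv.gz", index=False)
        scalars = pd.DataFrame(
            {"chain": chain, "Vrho": self.vrho_draws, "Deviance": self.deviance_draws}
        )
        scalars.to_csv(out_dir / "scalar_draws.csv.gz", index=False)
        pd.DataFrame(self.rho_draws).to_csv(out_dir / "rho_draws.csv.gz", index=False)
        with open(out_dir / "meta.json", "w") as fh:
            json.dump({**self.meta, "coef_names": self.coef_names}, fh, indent=2)

    @classmethod
    def load(cls, in_dir) -> "IcarFit":
        import json
        from pathlib import Path

        in_dir = Path(in_dir)
        with open(in_dir / "meta.json") as fh:
            meta = json.load(fh)
        coef_names = meta.pop("coef_names")
        beta = pd.read_csv(in_dir / "beta_draws.csv.gz")
        scalars = pd.read_csv(in_dir / "scalar_draws.csv.gz")
        rho = pd.read_csv(in_dir / "rho_draws.csv.gz").to_numpy()
        n_chains = int(beta["chain"].max()) + 1
        kept = len(beta) // n_chains
        b = beta[coef_names].to_numpy().reshape(n_chains, kept, -1)
        return cls(
            b,
            rho.reshape(n_chains, kept, -1),
            scalars["Vrho"].to_numpy().reshape(n_chains, kept),
            scalars["Deviance"].to_numpy().reshape(n_chains, kept),
            coef_names,
            meta,
        )


def build_cell_response(stack: CovariateStack, occ: pd.DataFrame) -> np.ndarray:
    """Cell-level response: 1 for valid cells holding >= 1 presence record,
    0 for every other valid cell (presence/background construction)."""
    grid = stack.empty_grid()
    pres = occ[occ["presence"] == 1]
    row, col = grid.rowcol_of(pres["lon"].to_numpy(), pres["lat"].to_numpy())
    inside = row >= 0
    hit = np.zeros(stack.mask.shape, dtype=bool)
    hit[row[inside], col[inside]] = True
    return (hit[stack.mask]).astype(int)


def _banded_structure(graph: NeighborGraph) -> tuple[int, np.ndarray, np.ndarray, np.ndarray]:
    ei, ej = [], []
    for i, nbrs in enumerate(graph.adjacency):
        for j in nbrs:
            if i < j:
                ei.append(i)
                ej.append(int(j))
    ei = np.array(ei, dtype=int)
    ej = np.array(ej, dtype=int)
    bw = int((ej - ei).max()) if len(ei) else 0
    return bw, ei, ej, graph.n_j.astype(float)


def fit_icar_bernoulli(
    y: np.ndarray,
    X: np.ndarray,
    graph: NeighborGraph,
    *,
    coef_names: list[str] | None = None,
    beta_var: float = 100.0,
    vrho_max: float | None = None,
    n_iter: int = 20000,
    burn_in: float = 0.25,
    thin: int = 10,
    n_chains: int = 2,
    seed: int = 0,
) -> IcarFit:
    """Fit the Bernoulli-logit iCAR occupancy model by Polya-Gamma Gibbs.

    ``X`` must include the intercept column first; non-intercept columns are
    expected to be standardized (a warning is issued otherwise).
    ``vrho_max`` bounds the uniform prior on the spatial variance; by
    default it is 10x the squared empirical logit of the observed
    prevalence (floored at 10).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n != graph.n or y.size != n:
        raise ValueError(f"X ({n} rows), y ({y.size}) and graph ({graph.n} cells) disagree")
    if not np.all(np.isfinite(X)):
        raise ValueError("design matrix contains non-finite values")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("y must be binary")
    if y.sum() == 0 or y.sum() == n:
        warnings.warn(
            "response is all-0 or all-1; the intercept is weakly identified "
            "and its credible interval will be wide",
            stacklevel=2,
        )
    nonconst = X.std(axis=0) > 0
    if np.any(nonconst):
        mu = np.abs(X[:, nonconst].mean(axis=0))
        sd = X[:, nonconst].std(axis=0)
        if np.any(mu > 0.25) or np.any((sd < 0.25) | (sd > 4.0)):
            warnings.warn("non-intercept covariates do not look standardized", stacklevel=2)
    if coef_names is None:
        coef_names = ["Intercept"] + [f"x{i}" for i in range(1, p)]

    if vrho_max is None:
        prev = np.clip(y.mean(), 1.0 / (n + 1.0), n / (n + 1.0))
        logit_prev = np.log(prev / (1.0 - prev))
        vrho_max = float(max(10.0, 10.0 * logit_prev**2))

    n_burn = int(round(burn_in * n_iter))
    kept_iters = range(n_burn, n_iter, thin)
    n_kept = len(kept_iters)
    if n_kept < 1:
        raise ValueError("no retained draws; lower burn_in or thin")

    bw, ei, ej, n_j = _banded_structure(graph)
    kappa = y - 0.5
    prior_prec_beta = np.eye(p) / beta_var
    # iCAR conditional for V_rho: InvGamma(shape=(n-1)/2 - 1, scale=ssq/2)
    # truncated to (0, vrho_max); flat prior on the variance.
    ig_shape = max((n - 1) / 2.0 - 1.0, 0.5)

    beta_out = np.empty((n_chains, n_kept, p))
    rho_out = np.empty((n_chains, n_kept, n))
    vrho_out = np.empty((n_chains, n_kept))
    dev_out = np.empty((n_chains, n_kept))

    for chain in range(n_chains):
        rng = np.random.default_rng([seed, chain, 0])
        pg_seeds = np.random.default_rng([seed, chain, 1]).integers(1, 2**31 - 1, size=n_iter)
        beta = np.zeros(p)
        rho = np.zeros(n)
        v = 1.0
        k = 0
        ab = np.zeros((bw + 1, n))
        for it in range(n_iter):
            psi = X @ beta + rho
            omega = pg_draws(psi, int(pg_seeds[it]))

            # beta | omega, rho
            prec_b = X.T @ (omega[:, None] * X) + prior_prec_beta
            Lb = np.linalg.cholesky(prec_b)
            mean_b = np.linalg.solve(prec_b, X.T @ (kappa - omega * rho))
            beta = mean_b + np.linalg.solve(Lb.T, rng.standard_normal(p))

            # rho | omega, beta, v  (block update; banded precision)
            ab[:] = 0.0
            ab[bw, :] = omega + n_j / v
            if len(ei):
                ab[bw + ei - ej, ej] = -1.0 / v
            ufac = cholesky_banded(ab, lower=False)
            rhs = kappa - omega * (X @ beta)
            mean_r = cho_solve_banded((ufac, False), rhs)
            z = rng.standard_normal(n)
            rho = mean_r + solve_banded((0, bw), ufac, z)
            rho -= rho.mean()

            # V_rho | rho: truncated inverse-gamma by inverse CDF
            ssq = float(np.sum((rho[ei] - rho[ej]) ** 2)) if len(ei) else 0.0
            scale = max(ssq / 2.0, 1e-30)
            cdf_max = gammaincc(ig_shape, scale / vrho_max)
            u = rng.random() * cdf_max
            if u <= 0.0:
                v = vrho_max
            else:
                v = float(scale / gammainccinv(ig_shape, u))
            v = min(max(v, 1e-12), vrho_max)

            if it >= n_burn and (it - n_burn) % thin == 0:
                beta_out[chain, k] = beta
                rho_out[chain, k] = rho
                vrho_out[chain, k] = v
                dev_out[chain, k] = deviance(beta, rho, y, X)
                k += 1

    meta = {
        "n_iter": n_iter,
        "burn_in": n_burn,
        "thin": thin,
        "n_chains": n_chains,
        "seed": seed,
        "beta_var": beta_var,
        "vrho_max": vrho_max,
        "sampler": "polya-gamma gibbs, blocked banded-Cholesky rho update",
    }
    return IcarFit(beta_out, rho_out, vrho_out, dev_out, list(coef_names), meta)


def deviance(beta: np.ndarray, rho: np.ndarray, y: np.ndarray, X: np.ndarray) -> float:
    """Bernoulli deviance -2 log-likelihood at given parameters (clamped logs)."""
    psi = np.asarray(X, float) @ np.asarray(beta, float) + np.asarray(rho, float)
    pi = expit(psi)
    y = np.asarray(y, float)
    ll = y * np.log(np.clip(pi, _LOG_CLAMP, 1.0)) + (1.0 - y) * np.log(
        np.clip(1.0 - pi, _LOG_CLAMP, 1.0)
    )
    return float(-2.0 * ll.sum())


def dic(fit: IcarFit, y: np.ndarray, X: np.ndarray) -> tuple[float, float, float]:
    """Deviance information criterion: (DIC, pD, D_bar).

    D_bar is the posterior mean deviance; pD = D_bar - D(posterior-mean
    parameters); DIC = D_bar + pD.
    """
    if fit.n_kept < 100:
        raise ValueError(f"need >= 100 retained draws, have {fit.n_kept}")
    d_bar = float(fit.deviance_draws.mean())
    d_hat = deviance(fit.beta_draws.mean(axis=0), fit.rho_draws.mean(axis=0), y, X)
    p_d = d_bar - d_hat
    return d_bar + p_d, p_d, d_bar


def split_rhat(draws: np.ndarray) -> float:
    """Split-R-hat of a scalar parameter; draws shaped (chain, draw)."""
    draws = np.asarray(draws, float)
    if draws.ndim == 1:
        draws = draws[None, :]
    half = draws.shape[1] // 2
    if half < 2:
        return np.nan
    chains = np.concatenate([draws[:, :half], draws[:, half : 2 * half]], axis=0)
    m, nn = chains.shape
    means = chains.mean(axis=1)
    w = chains.var(axis=1, ddof=1).mean()
    b = nn * means.var(ddof=1)
    if w <= 0:
        return 1.0 if b <= 0 else np.inf
    var_plus = (nn - 1) / nn * w + b / nn
    return float(np.sqrt(var_plus / w))


def effective_sample_size(draws: np.ndarray) -> float:
    """Bulk effective sample size via ArviZ."""
    import arviz as az

    draws = np.asarray(draws, float)
    if draws.ndim == 1:
        draws = draws[None, :]
    if draws.shape[0] == 1:
        half = draws.shape[1] // 2
        draws = np.stack([draws[0, :half], draws[0, half : 2 * half]])
    return float(az.ess(draws))


def posterior_summary(fit: IcarFit, force: bool = False) -> pd.DataFrame:
    """Posterior mean, SD and central 95% interval per fixed effect, plus
    Vrho and Deviance rows. Refuses to summarize an unconverged fit
    (max split-R-hat > 1.1) unless ``force`` is set."""
    if fit.n_kept < 100:
        raise ValueError(f"need >= 100 retained draws, have {fit.n_kept}")
    rhat = fit.max_rhat()
    if not force and rhat > 1.1:
        raise RuntimeError(
            f"chains look unconverged (max split-R-hat = {rhat:.3f} > 1.1); "
            "run longer or pass force=True"
        )
    rows = {}
    draws_by_name = {nm: fit.beta_draws[:, j] for j, nm in enumerate(fit.coef_names)}
    draws_by_name["Vrho"] = fit.vrho_draws
    draws_by_name["Deviance"] = fit.deviance_draws
    for nm, d in draws_by_name.items():
        rows[nm] = {
            "Mean": float(d.mean()),
            "SD": float(d.std(ddof=1)),
            "Q0.025": float(np.quantile(d, 0.025)),
            "Q0.975": float(np.quantile(d, 0.975)),
        }
    out = pd.DataFrame(rows).T[["Mean", "SD", "Q0.025", "Q0.975"]]
    out.attrs["max_split_rhat"] = rhat
    out.attrs["min_bulk_ess"] = fit.min_ess()
    return out


def spatial_effect_map(fit: IcarFit, stack: CovariateStack) -> RasterGrid:
    """Per-cell posterior mean of the spatial effect on the stack's grid."""
    if fit.rho.shape[-1] != stack.n_valid:
        raise ValueError(
            f"fit has {fit.rho.shape[-1]} cells but stack has {stack.n_valid} valid cells"
        )
    grid = stack.empty_grid()
    grid.values[stack.mask] = fit.rho_draws.mean(axis=0)
    return grid
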
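"""Hierarchical Bayesian fit of the washout model.

Each bird gets its own fed endpoint δ¹³C₀ and fasted asymptote δ¹³C∞; a
single retention time τ is shared by every bird in the fit, and a single
residual sd σ describes Gaussian measurement error:

    δ¹³C_obs(bird, t) ~ Normal(δ∞ᵢ − (δ∞ᵢ − δ₀ᵢ)·e^(−t/τ), σ)

Priors are uniform: δ ∈ (−30, −10)‰ for every endpoint, τ ∈ (0, 20) min,
σ ∈ (0, 5)‰. Sampling is Metropolis-within-Gibbs with per-parameter Gaussian
random-walk proposals, vectorized across birds (endpoints of different birds
are conditionally independent given τ and σ, so their accept/reject steps
run component-wise). Proposal scales adapt toward ~30% acceptance during
burn-in only, so retained draws come from a fixed kernel.

Convergence is assessed with the rank-normalized split-R̂ diagnostic
(via arviz); the conventional pass threshold is R̂ < 1.1 for all parameters.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import DataAdequacyError, InsufficientSamplesError, ValidationError
from .types import BirdSeries

_ADAPT_INTERVAL = 100
_TARGET_ACCEPT = 0.30


@dataclass(frozen=True)
class PriorSpec:
    """Uniform prior bounds for every parameter class."""

    tau_bounds: tuple[float, float] = (0.0, 20.0)
    delta_bounds: tuple[float, float] = (-30.0, -10.0)
    sigma_bounds: tuple[float, float] = (0.0, 5.0)

    def __post_init__(self):
        for name in ("tau_bounds", "delta_bounds", "sigma_bounds"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValidationError(f"{name}: lower bound must be < upper bound")


@dataclass(frozen=True)
class MCMCConfig:
    """Chain configuration; defaults follow the published analysis."""

    n_chains: int = 3
    n_iter: int = 10_000
    n_burn: int = 1_000
    thin: int = 3
    seed: int = 0

    def __post_init__(self):
        if not (self.n_iter > self.n_burn >= 0):
            raise ValidationError("need n_iter > n_burn >= 0")
        if self.thin < 1:
            raise ValidationError("thin must be >= 1")
        if self.n_chains < 2:
            raise ValidationError("need at least 2 chains")

    @property
    def n_retained(self) -> int:
        return int(np.ceil((self.n_iter - self.n_burn) / self.thin))


@dataclass
class PosteriorSamples:
    """Retained MCMC draws, organized by chain.

    ``d13c_0`` and ``d13c_inf`` have shape (chains, draws, birds), ``tau``
    and ``sigma`` shape (chains, draws). The single τ/σ column is shared by
    all birds within an iteration — the hierarchical pooling contract.
    """

    bird_ids: list[str]
    meta: pd.DataFrame  # bird_id, species, sex, year, site
    d13c_0: np.ndarray
    d13c_inf: np.ndarray
    tau: np.ndarray
    sigma: np.ndarray
    priors: PriorSpec
    config: MCMCConfig

    @property
    def n_chains(self) -> int:
        return self.tau.shape[0]

    @property
    def n_draws(self) -> int:
        return self.tau.shape[1]

    def bird_draws(self, bird_id: str, parameter: str) -> np.ndarray:
        """Flattened (all chains) draws of one bird's parameter."""
        j = self.bird_ids.index(bird_id)
        arr = getattr(self, parameter)
        return arr[:, :, j].reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long table: chain, draw, parameter, bird_id, species, year, value."""
        meta = self.meta.set_index("bird_id")
        rows = []
        chains, draws, nb = self.d13c_0.shape
        chain_idx = np.repeat(np.arange(chains), draws)
        draw_idx = np.tile(np.arange(draws), chains)
        for name, arr in (("tau", self.tau), ("sigma", self.sigma)):
            rows.append(
                pd.DataFrame(
                    {
                        "chain": chain_idx,
                        "draw": draw_idx,
                        "parameter": name,
                        "bird_id": "",
                        "species": "",
                        "year": -1,
                        "value": arr.reshape(-1),
                    }
                )
            )
        for name, arr in (("d13c_0", self.d13c_0), ("d13c_inf", self.d13c_inf)):
            for j, bid in enumerate(self.bird_ids):
                rows.append(
                    pd.DataFrame(
                        {
                            "chain": chain_idx,
                            "draw": draw_idx,
                            "parameter": name,
                            "bird_id": bid,
                            "species": meta.loc[bid, "species"],
                            "year": int(meta.loc[bid, "year"]),
                            "value": arr[:, :, j].reshape(-1),
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        priors: PriorSpec | None = None,
        config: MCMCConfig | None = None,
    ) -> "PosteriorSamples":
        """Rebuild a PosteriorSamples from the tidy long table."""
        chains = int(df["chain"].max()) + 1
        draws = int(df["draw"].max()) + 1
        per_bird = df[df["parameter"] == "d13c_0"]
        bird_ids = sorted(per_bird["bird_id"].unique())
        meta = (
            per_bird.groupby("bird_id")
            .agg(species=("species", "first"), year=("year", "first"))
            .reset_index()
        )
        meta["sex"] = "unknown"
        meta["site"] = ""

        def grab(parameter: str, bird_id: str | None = None) -> np.ndarray:
            sel = df["parameter"] == parameter
            if bird_id is not None:
                sel &= df["bird_id"] == bird_id
            sub = df[sel].sort_values(["chain", "draw"])
            return sub["value"].to_numpy().reshape(chains, draws)

        d0 = np.stack([grab("d13c_0", b) for b in bird_ids], axis=-1)
        dinf = np.stack([grab("d13c_inf", b) for b in bird_ids], axis=-1)
        return cls(
            bird_ids=bird_ids,
            meta=meta[["bird_id", "species", "sex", "year", "site"]],
            d13c_0=d0,
            d13c_inf=dinf,
            tau=grab("tau"),
            sigma=grab("sigma"),
            priors=priors or PriorSpec(),
            config=config or MCMCConfig(),
        )


def _prefit_sigma(t: np.ndarray, y: np.ndarray, bird_slices: list[slice]) -> float:
    """Residual sd of independent per-bird least-squares curve fits."""

    def model(tt, d0, dinf, tau):
        return dinf - (dinf - d0) * np.exp(-tt / tau)

    residuals: list[np.ndarray] = []
    for sl in bird_slices:
        tt, yy = t[sl], y[sl]
        if tt.size < 4:
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    model,
                    tt,
                    yy,
                    p0=[yy[0], yy[-1], 3.0],
                    bounds=([-40, -40, 1e-3], [0, 0, 60]),
                    maxfev=2000,
                )
            residuals.append(yy - model(tt, *popt))
        except Exception:
            continue
    if not residuals:
        return 0.5
    resid = np.concatenate(residuals)
    return float(max(np.std(resid), 1e-3))


def fit_hierarchical(
    data: Sequence[BirdSeries],
    priors: PriorSpec = PriorSpec(),
    mcmc: MCMCConfig = MCMCConfig(),
) -> PosteriorSamples:
    """Sample the joint posterior of all per-bird endpoints, shared τ, and σ.

    Deterministic given (data, priors, mcmc): chains use independent streams
    spawned from ``mcmc.seed`` and run sequentially.
    """
    data = list(data)
    short = [b.bird_id for b in data if len(b) < 2]
    if short:
        raise DataAdequacyError(short)
    if not data:
        raise ValidationError("empty dataset")

    bird_ids = [b.bird_id for b in data]
    nb = len(bird_ids)
    t = np.concatenate([np.asarray(b.times, float) for b in data])
    y = np.concatenate([np.asarray(b.d13c_values, float) for b in data])
    counts = np.array([len(b) for b in data])
    offsets = np.concatenate([[0], np.cumsum(counts)])
    bird_idx = np.repeat(np.arange(nb), counts)
    bird_slices = [slice(offsets[j], offsets[j + 1]) for j in range(nb)]
    n_obs = y.size

    if np.ptp(y) == 0:
        warnings.warn(
            "all observed d13c values are identical; likelihood is degenerate "
            "in the endpoints, proceeding anyway",
            stacklevel=2,
        )

    dlo, dhi = priors.delta_bounds
    tlo, thi = priors.tau_bounds
    slo, shi = priors.sigma_bounds
    sigma0 = float(np.clip(_prefit_sigma(t, y, bird_slices), slo + 1e-6, shi - 1e-6))

    y_first = np.array([y[sl][0] for sl in bird_slices])
    y_last = np.array([y[sl][-1] for sl in bird_slices])

    cfg = mcmc
    n_ret = cfg.n_retained
    out_d0 = np.empty((cfg.n_chains, n_ret, nb))
    out_dinf = np.empty((cfg.n_chains, n_ret, nb))
    out_tau = np.empty((cfg.n_chains, n_ret))
    out_sigma = np.empty((cfg.n_chains, n_ret))

    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)]
    margin = 1e-3 * (dhi - dlo)

    for c, rng in enumerate(streams):
        # overdispersed starts: prefit-style values plus per-chain jitter
        d0 = np.clip(y_first + rng.normal(0, 0.5, nb), dlo + margin, dhi - margin)
        dinf = np.clip(y_last + rng.normal(0, 0.5, nb), dlo + margin, dhi - margin)
        tau = float(np.clip(3.0 * np.exp(rng.normal(0, 0.2)), tlo + 1e-3, thi - 1e-3))
        sigma = float(np.clip(sigma0 * np.exp(rng.normal(0, 0.2)), slo + 1e-6, shi - 1e-6))

        step_d0 = np.full(nb, 0.5)
        step_dinf = np.full(nb, 0.5)
        step_tau = 0.3
        step_sigma = max(0.25 * sigma0, 0.02)
        acc_d0 = np.zeros(nb)
        acc_dinf = np.zeros(nb)
        acc_tau = 0.0
        acc_sigma = 0.0

        E = np.exp(-t / tau)
        mu = dinf[bird_idx] - (dinf - d0)[bird_idx] * E
        sse = np.bincount(bird_idx, weights=(y - mu) ** 2, minlength=nb)

        k = 0
        for it in range(cfg.n_iter):
            inv2s2 = 1.0 / (2.0 * sigma * sigma)

            # per-bird d13c_0 block: dmu/d d0 = E
            prop = d0 + step_d0 * rng.standard_normal(nb)
            shift = (prop - d0)[bird_idx] * E
            sse_new = np.bincount(bird_idx, weights=(y - mu - shift) ** 2, minlength=nb)
            logu = np.log(rng.random(nb))
            ok = (prop > dlo) & (prop < dhi)
            accept = ok & (logu < -(sse_new - sse) * inv2s2)
            if accept.any():
                mu = mu + np.where(accept[bird_idx], shift, 0.0)
                d0 = np.where(accept, prop, d0)
                sse = np.where(accept, sse_new, sse)
            acc_d0 += accept

            # per-bird d13c_inf block: dmu/d dinf = 1 - E
            prop = dinf + step_dinf * rng.standard_normal(nb)
            shift = (prop - dinf)[bird_idx] * (1.0 - E)
            sse_new = np.bincount(bird_idx, weights=(y - mu - shift) ** 2, minlength=nb)
            logu = np.log(rng.random(nb))
            ok = (prop > dlo) & (prop < dhi)
            accept = ok & (logu < -(sse_new - sse) * inv2s2)
            if accept.any():
                mu = mu + np.where(accept[bird_idx], shift, 0.0)
                dinf = np.where(accept, prop, dinf)
                sse = np.where(accept, sse_new, sse)
            acc_dinf += accept

            # shared tau: full-likelihood scalar update
            prop_tau = tau + step_tau * rng.standard_normal()
            logu1 = np.log(rng.random())
            if tlo < prop_tau < thi:
                E_new = np.exp(-t / prop_tau)
                mu_new = dinf[bird_idx] - (dinf - d0)[bird_idx] * E_new
                sse_new_v = np.bincount(bird_idx, weights=(y - mu_new) ** 2, minlength=nb)
                if logu1 < -(sse_new_v.sum() - sse.sum()) * inv2s2:
                    tau, E, mu, sse = float(prop_tau), E_new, mu_new, sse_new_v
                    acc_tau += 1

            # residual sd: uniform prior, normal likelihood
            prop_sigma = sigma + step_sigma * rng.standard_normal()
            logu2 = np.log(rng.random())
            if slo < prop_sigma < shi:
                total = sse.sum()
                logr = (
                    -n_obs * (np.log(prop_sigma) - np.log(sigma))
                    - total / (2 * prop_sigma * prop_sigma)
                    + total * inv2s2
                )
                if logu2 < logr:
                    sigma = float(prop_sigma)
                    acc_sigma += 1

            # burn-in-only step-size adaptation toward ~30% acceptance
            if it < cfg.n_burn and (it + 1) % _ADAPT_INTERVAL == 0:
                factor = lambda rate: np.exp(np.clip(rate - _TARGET_ACCEPT, -0.5, 0.5))
                step_d0 *= factor(acc_d0 / _ADAPT_INTERVAL)
                step_dinf *= factor(acc_dinf / _ADAPT_INTERVAL)
                step_tau *= float(factor(acc_tau / _ADAPT_INTERVAL))
                step_sigma *= float(factor(acc_sigma / _ADAPT_INTERVAL))
                acc_d0[:] = 0
                acc_dinf[:] = 0
                acc_tau = 0.0
                acc_sigma = 0.0

            if it >= cfg.n_burn and (it - cfg.n_burn) % cfg.thin == 0:
                out_d0[c, k] = d0
                out_dinf[c, k] = dinf
                out_tau[c, k] = tau
                out_sigma[c, k] = sigma
                k += 1

    meta = pd.DataFrame(
        {
            "bird_id": bird_ids,
            "species": [b.species.value for b in data],
            "sex": [b.sex.value for b in data],
            "year": [b.year for b in data],
            "site": [b.site for b in data],
        }
    )
    return PosteriorSamples(
        bird_ids=bird_ids,
        meta=meta,
        d13c_0=out_d0,
        d13c_inf=out_dinf,
        tau=out_tau,
        sigma=out_sigma,
        priors=priors,
        config=cfg,
    )


def rhat_from_chains(chains: np.ndarray) -> float:
    """Rank-normalized split-R̂ for one parameter's (chains, draws) array.

    Returns NaN (with a warning) when total variance is zero — the
    diagnostic is undefined there, never silently 1.0.
    """
    import arviz as az

    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise InsufficientSamplesError("R-hat needs >= 2 chains")
    if x.shape[1] < 10:
        raise InsufficientSamplesError("R-hat needs >= 10 retained draws per chain")
    if np.ptp(x) == 0:
        warnings.warn("zero total variance: R-hat undefined", stacklevel=2)
        return float("nan")
    return float(az.rhat(x))


def rhat(samples: PosteriorSamples, parameter: str) -> float | dict[str, float]:
    """R̂ for one parameter: scalar for tau/sigma, per-bird dict otherwise."""
    if parameter in ("tau", "sigma"):
        return rhat_from_chains(getattr(samples, parameter))
    if parameter in ("d13c_0", "d13c_inf"):
        arr = getattr(samples, parameter)
        return {
            bid: rhat_from_chains(arr[:, :, j])
            for j, bid in enumerate(samples.bird_ids)
        }
    raise ValidationError(f"unknown parameter {parameter!r}")


@dataclass
class ConvergenceReport:
    rhat: dict[str, float]
    threshold: float = 1.1
    passed: bool = field(init=False)

    def __post_init__(self):
        values = np.array(list(self.rhat.values()), dtype=float)
        # NaN (undefined diagnostic) counts as a failure, never a silent pass
        self.passed = bool(values.size) and bool(
            np.all(np.isfinite(values)) and np.all(values < self.threshold)
        )

    @property
    def max_rhat(self) -> float:
        return float(np.nanmax(list(self.rhat.values())))


def convergence_check(samples: PosteriorSamples, threshold: float = 1.1) -> ConvergenceReport:
    """R̂ for every parameter in the fit; passes iff all are < threshold."""
    values: dict[str, float] = {
        "tau": rhat_from_chains(samples.tau),
        "sigma": rhat_from_chains(samples.sigma),
    }
    for name in ("d13c_0", "d13c_inf"):
        arr = getattr(samples, name)
        for j, bid in enumerate(samples.bird_ids):
            values[f"{name}[{bid}]"] = rhat_from_chains(arr[:, :, j])
    return ConvergenceReport(rhat=values, threshold=threshold)
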
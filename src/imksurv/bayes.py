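"""Bayesian joint fitting of a parental + radioresistant cell-line family.

The eight free parameters are the parental progeny LQ coefficients and SLDR
rate [alpha0p, beta0p, (a+c)_p], the shared stem-cell coefficients
[alpha0s, beta0s], the SLDR enhancement ratio w_SLDR of the resistant line,
and the stem fractions of the two lines [f_s_parent, f_s_resistant].  Stem
cells of both lines repair at (a+c)_H = w_SLDR * (a+c)_p — the tie holds
structurally at every likelihood evaluation — and the resistant line's
progeny coefficients are alpha0p/w_SLDR and beta0p/w_SLDR.

The likelihood is Gaussian on the -ln S scale::

    P(d | theta) = prod_i N(-ln S_obs,i ; -ln S_model,i(theta), sigma^2)

with sigma either fixed (default: the pooled replicate SD of the data) or
sampled under a weak half-normal prior.  Priors follow the two-stage design
of the analysis workflow: uniform boxes for the LQ coefficients and w_SLDR,
a normal prior on (a+c)_p carried over from the split-dose stage, and
truncated-normal priors on the stem fractions taken from flow-cytometry
summaries.  Stem coefficients are constrained below the progeny ones
(alpha0s < alpha0p, beta0s < beta0p).

Sampling uses seeded Gaussian random-walk Metropolis with per-parameter
proposal scales adapted during burn-in only (frozen afterwards, preserving
detailed balance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import MicrodosimetricContext, PopulationParams, gamma_coefficient
from .datasets import SurvivalDataset
from .exceptions import SamplerError
from .protocols import AcuteDelivery, Delivery
from .reference import FlowCytometryObservation

__all__ = [
    "PARAM_NAMES",
    "ParameterVector",
    "PriorSpec",
    "LikelihoodConfig",
    "SamplerConfig",
    "FamilyLikelihood",
    "log_likelihood",
    "metropolis_acceptance",
    "fit_family",
    "FamilyFit",
    "PosteriorSummary",
    "r_squared",
]

PARAM_NAMES = (
    "alpha0p",
    "beta0p",
    "repair_p",
    "alpha0s",
    "beta0s",
    "w_sldr",
    "f_s_parent",
    "f_s_resistant",
)

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ParameterVector:
    """One point in the eight-dimensional family parameter space."""

    alpha0p: float
    beta0p: float
    repair_p: float
    alpha0s: float
    beta0s: float
    w_sldr: float
    f_s_parent: float
    f_s_resistant: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "ParameterVector":
        return cls(**dict(zip(PARAM_NAMES, map(float, arr))))

    @property
    def repair_H(self) -> float:
        """Stem-cell SLDR rate (a+c)_H = w_SLDR * (a+c)_p, h^-1."""
        return self.w_sldr * self.repair_p

    @property
    def alpha0p_star(self) -> float:
        """Resistant-line progeny alpha0, Gy^-1."""
        return self.alpha0p / self.w_sldr

    @property
    def beta0p_star(self) -> float:
        """Resistant-line progeny beta0, Gy^-2."""
        return self.beta0p / self.w_sldr

    def satisfies_constraints(self, priors: "PriorSpec") -> bool:
        return np.isfinite(priors.log_prior(self.to_array()))


@dataclass(frozen=True)
class PriorSpec:
    """Prior distributions and hard constraints for a family fit.

    Uniform boxes for the LQ coefficients and w_SLDR; normal prior for the
    parental SLDR rate (mean/SD from the split-dose stage); truncated-normal
    priors on [0, 1] for the stem fractions (mean/SD from flow cytometry).
    A prior SD of zero (or a zero-width box) pins the parameter at its mean.
    """

    alpha_bounds: tuple[float, float] = (0.0, 1.0)
    beta_bounds: tuple[float, float] = (0.0, 0.5)
    w_bounds: tuple[float, float] = (1.0, 5.0)
    repair_prior: tuple[float, float] = (1.5, 0.7)
    f_s_parent_prior: tuple[float, float] = (0.01, 0.01)
    f_s_resistant_prior: tuple[float, float] = (0.10, 0.05)
    #: half-normal scale for sigma when it is sampled
    sigma_scale: float = 0.5
    #: require alpha0s < alpha0p and beta0s < beta0p
    stem_below_progeny: bool = True
    #: parameters pinned to point masses, e.g. (("w_sldr", 1.0),)
    fixed: tuple[tuple[str, float], ...] = ()

    def fixed_dict(self) -> dict[str, float]:
        return dict(self.fixed)

    @classmethod
    def from_experiments(
        cls,
        repair_rate: float,
        repair_sd: float,
        flow_parent: FlowCytometryObservation,
        flow_resistant: FlowCytometryObservation,
        **kwargs,
    ) -> "PriorSpec":
        """Assemble priors from split-dose and flow-cytometry summaries."""
        return cls(
            repair_prior=(repair_rate, repair_sd),
            f_s_parent_prior=(flow_parent.mean, flow_parent.sd),
            f_s_resistant_prior=(flow_resistant.mean, flow_resistant.sd),
            **kwargs,
        )

    def _box(self, name: str) -> tuple[float, float]:
        return {
            "alpha0p": self.alpha_bounds,
            "beta0p": self.beta_bounds,
            "alpha0s": self.alpha_bounds,
            "beta0s": self.beta_bounds,
            "w_sldr": self.w_bounds,
        }[name]

    def log_prior(self, theta: np.ndarray, sigma: float | None = None) -> float:
        """Log prior density (up to constants that cancel in Metropolis)."""
        a0p, b0p, rep, a0s, b0s, w, fsp, fsr = theta
        for name, val in self.fixed:
            if theta[PARAM_NAMES.index(name)] != val:
                return -np.inf
        for val, name in (
            (a0p, "alpha0p"),
            (b0p, "beta0p"),
            (a0s, "alpha0s"),
            (b0s, "beta0s"),
            (w, "w_sldr"),
        ):
            lo, hi = self._box(name)
            if not lo <= val <= hi:
                return -np.inf
        if rep <= 0:
            return -np.inf
        if self.stem_below_progeny and (a0s >= a0p or b0s >= b0p):
            return -np.inf
        lp = 0.0
        mu, sd = self.repair_prior
        if sd == 0:
            if rep != mu:
                return -np.inf
        else:
            lp += -0.5 * ((rep - mu) / sd) ** 2 - math.log(sd)
        for fs, (mu, sd) in (
            (fsp, self.f_s_parent_prior),
            (fsr, self.f_s_resistant_prior),
        ):
            if not 0.0 <= fs <= 1.0:
                return -np.inf
            if sd == 0:
                if fs != mu:
                    return -np.inf
            else:
                lp += -0.5 * ((fs - mu) / sd) ** 2 - math.log(sd)
        if sigma is not None:
            if sigma <= 0:
                return -np.inf
            lp += -0.5 * (sigma / self.sigma_scale) ** 2
        return lp

    def initial_point(self) -> np.ndarray:
        """A constraint-satisfying starting point near the prior centre."""
        alo, ahi = self.alpha_bounds
        blo, bhi = self.beta_bounds
        wlo, whi = self.w_bounds
        point = np.array(
            [
                alo + 0.30 * (ahi - alo),
                blo + 0.30 * (bhi - blo),
                max(self.repair_prior[0], 1e-3),
                alo + 0.10 * (ahi - alo),
                blo + 0.10 * (bhi - blo),
                wlo + 0.10 * (whi - wlo),
                min(max(self.f_s_parent_prior[0], 0.0), 1.0),
                min(max(self.f_s_resistant_prior[0], 0.0), 1.0),
            ]
        )
        for name, val in self.fixed:
            point[PARAM_NAMES.index(name)] = val
        return point

    def proposal_scales(self) -> np.ndarray:
        """Initial per-parameter random-walk scales (zero pins a parameter)."""
        def box_scale(lo, hi):
            return 0.05 * (hi - lo)

        scales = np.array(
            [
                box_scale(*self.alpha_bounds),
                box_scale(*self.beta_bounds),
                0.5 * self.repair_prior[1],
                box_scale(*self.alpha_bounds),
                box_scale(*self.beta_bounds),
                box_scale(*self.w_bounds),
                0.5 * self.f_s_parent_prior[1],
                0.5 * self.f_s_resistant_prior[1],
            ]
        )
        for name, _ in self.fixed:
            scales[PARAM_NAMES.index(name)] = 0.0
        return scales


@dataclass(frozen=True)
class LikelihoodConfig:
    """Residual model on the -ln S scale.

    ``sigma`` is the Gaussian residual SD; ``estimate_sigma=True`` adds sigma
    to the sampled parameters under a half-normal prior, otherwise it stays
    fixed (callers typically use the pooled replicate SD of the data).
    """

    sigma: float = 0.1
    estimate_sigma: bool = False

    def __post_init__(self) -> None:
        if not self.estimate_sigma and not self.sigma > 0:
            raise ValueError("fixed sigma must be positive")


class FamilyLikelihood:
    """Pre-compiled Gaussian likelihood of one family's survival data.

    Survival predictions use the acute closed form directly when every
    record's delivery is instantaneous (the common case for dose-response
    fitting) and fall back to full protocol evaluation otherwise.
    """

    def __init__(
        self,
        parent_data: SurvivalDataset,
        resistant_data: SurvivalDataset | None,
        ctx: MicrodosimetricContext,
        deliveries: Mapping[str, Delivery] | None = None,
    ):
        self.gamma = gamma_coefficient(ctx)
        self.deliveries = dict(deliveries or {})
        self.deliveries.setdefault("acute", AcuteDelivery())
        self._lines = []
        for data, resistant in ((parent_data, False), (resistant_data, True)):
            if data is None:
                continue
            df = data.records
            entry = {
                "resistant": resistant,
                "dose": df["dose_Gy"].to_numpy(dtype=float),
                "obs": df["neg_log_S"].to_numpy(dtype=float),
                "protocol": df["protocol_id"].to_numpy(),
            }
            entry["all_acute"] = all(
                isinstance(self._delivery(p), AcuteDelivery)
                and self._delivery(p).dose_rate_gy_min is None
                for p in np.unique(entry["protocol"])
            )
            self._lines.append(entry)
        if not self._lines:
            raise ValueError("at least one dataset is required")
        self.N = sum(len(e["obs"]) for e in self._lines)

    def _delivery(self, protocol_id: str) -> Delivery:
        try:
            return self.deliveries[protocol_id]
        except KeyError:
            raise KeyError(
                f"protocol {protocol_id!r} has no registered delivery; "
                f"known: {sorted(self.deliveries)}"
            )

    def _neg_log_S_line(self, entry: dict, theta: np.ndarray) -> np.ndarray:
        a0p, b0p, rep, a0s, b0s, w, fsp, fsr = theta
        f_s = fsr if entry["resistant"] else fsp
        if entry["resistant"]:
            ap, bp, kp = a0p / w, b0p / w, w * rep
        else:
            ap, bp, kp = a0p, b0p, rep
        kH = w * rep
        d = entry["dose"]
        g = self.gamma
        if entry["all_acute"]:
            ylp = (ap + g * bp) * d + bp * d * d
            yls = (a0s + g * b0s) * d + b0s * d * d
        else:
            prog = PopulationParams(ap, bp, kp)
            stem = PopulationParams(a0s, b0s, kH)
            ylp = np.empty_like(d)
            yls = np.empty_like(d)
            cache: dict[tuple, tuple[float, float]] = {}
            for i, (dose, pid) in enumerate(zip(d, entry["protocol"])):
                key = (pid, dose)
                if key not in cache:
                    dlv = self._delivery(pid)
                    cache[key] = (
                        dlv.neg_log_survival(prog, g, dose),
                        dlv.neg_log_survival(stem, g, dose),
                    )
                ylp[i], yls[i] = cache[key]
        S = (1.0 - f_s) * np.exp(-ylp) + f_s * np.exp(-yls)
        return -np.log(S)

    def predicted(self, theta: np.ndarray) -> list[np.ndarray]:
        """Model -ln S for each line's records, in dataset order."""
        return [self._neg_log_S_line(e, theta) for e in self._lines]

    def log_likelihood(self, theta: np.ndarray, sigma: float) -> float:
        total = 0.0
        for entry in self._lines:
            resid = entry["obs"] - self._neg_log_S_line(entry, theta)
            total += -0.5 * float(resid @ resid) / (sigma * sigma)
        total -= self.N * (math.log(sigma) + _LOG_SQRT_2PI)
        return total


def log_likelihood(
    data: SurvivalDataset,
    theta: ParameterVector,
    cfg: LikelihoodConfig,
    ctx: MicrodosimetricContext,
    deliveries: Mapping[str, Delivery] | None = None,
    resistant: bool = False,
) -> float:
    """Gaussian log likelihood of one line's data under the family model.

    Constraint violations yield ``-inf`` (handled as rejection by the
    sampler), never an exception.
    """
    arr = theta.to_array() if isinstance(theta, ParameterVector) else np.asarray(theta)
    if np.any(~np.isfinite(arr)) or np.any(arr[:6] <= 0):
        return -np.inf
    if not (0 <= arr[6] <= 1 and 0 <= arr[7] <= 1):
        return -np.inf
    if arr[3] >= arr[0] or arr[4] >= arr[1]:  # stem coefficients below progeny
        return -np.inf
    lik = FamilyLikelihood(
        parent_data=None if resistant else data,
        resistant_data=data if resistant else None,
        ctx=ctx,
        deliveries=deliveries,
    )
    return lik.log_likelihood(arr, cfg.sigma)


def metropolis_acceptance(
    log_post_candidate: float, log_post_current: float
) -> float:
    """Metropolis acceptance probability min(1, P_cand / P_curr), in log space.

    With a symmetric proposal the transition ratio is the posterior-density
    ratio; a candidate violating constraints (density zero) is never
    accepted, including when both densities are zero.
    """
    if not np.isfinite(log_post_candidate):
        return 0.0
    if not np.isfinite(log_post_current):
        return 1.0
    return float(min(1.0, math.exp(min(log_post_candidate - log_post_current, 0.0))))


@dataclass(frozen=True)
class SamplerConfig:
    """Random-walk Metropolis settings.

    Defaults: 50k iterations with the first 20% discarded as burn-in, during
    which per-parameter proposal scales are adapted toward a 20-40% overall
    acceptance rate; adaptation is frozen afterwards.
    """

    n_iter: int = 50_000
    burn_in_fraction: float = 0.2
    thin: int = 1
    target_acceptance: float = 0.30
    adapt_interval: int = 500
    min_acceptance: float = 0.01

    @property
    def n_burn(self) -> int:
        return int(self.n_iter * self.burn_in_fraction)


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior means/SDs, chain diagnostics, and per-line goodness of fit."""

    table: pd.DataFrame  # index: parameter, columns: mean, sd
    acceptance_rate: float
    ess: pd.Series
    r2: dict[str, float]
    sigma: float
    n_samples: int
    seed: int | None

    def mean_vector(self) -> ParameterVector:
        return ParameterVector.from_array(
            [self.table.loc[n, "mean"] for n in PARAM_NAMES]
        )


@dataclass(frozen=True)
class FamilyFit:
    """Result of a family fit: retained chain plus posterior summary."""

    chain: pd.DataFrame
    summary: PosteriorSummary
    priors: PriorSpec
    likelihood_config: LikelihoodConfig


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot on the -ln S scale."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("observed and predicted must be equal-length, size >= 2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 is undefined: observed values have zero variance")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def _effective_sample_size(chain: pd.DataFrame) -> pd.Series:
    import arviz as az

    ess = {}
    for col in chain.columns:
        x = chain[col].to_numpy()
        if np.std(x) == 0:
            ess[col] = float(len(x))
        else:
            ess[col] = float(az.ess(x[np.newaxis, :]))
    return pd.Series(ess)


def fit_family(
    parent_data: SurvivalDataset,
    resistant_data: SurvivalDataset | None,
    priors: PriorSpec,
    ctx: MicrodosimetricContext,
    deliveries: Mapping[str, Delivery] | None = None,
    likelihood: LikelihoodConfig | None = None,
    config: SamplerConfig | None = None,
    seed: int | None = None,
) -> FamilyFit:
    """Joint Metropolis fit of a parental (+ optional resistant) line pair.

    If ``likelihood`` is omitted, sigma is fixed at the pooled replicate SD
    of the combined data.  The run is reproducible bit-for-bit at a fixed
    seed.  Raises :class:`SamplerError` if the post-adaptation acceptance
    rate collapses below ``config.min_acceptance``.
    """
    config = config or SamplerConfig()
    if likelihood is None:
        frames = [parent_data.records]
        if resistant_data is not None:
            frames.append(resistant_data.records)
        pooled = SurvivalDataset(pd.concat(frames, ignore_index=True))
        likelihood = LikelihoodConfig(sigma=pooled.pooled_replicate_sd())
    lik = FamilyLikelihood(parent_data, resistant_data, ctx, deliveries)
    rng = np.random.default_rng(seed)

    sample_sigma = likelihood.estimate_sigma
    theta = priors.initial_point()
    sigma0 = likelihood.sigma if likelihood.sigma > 0 else priors.sigma_scale

    def log_post(th: np.ndarray, sg: float) -> float:
        lp = priors.log_prior(th, sg if sample_sigma else None)
        if not np.isfinite(lp):
            return -np.inf
        return lp + lik.log_likelihood(th, sg)

    scales = priors.proposal_scales()
    free = scales > 0
    current_lp = log_post(theta, sigma0)
    tries = 0
    while not np.isfinite(current_lp):
        jitter = np.where(free, rng.uniform(0.5, 1.5, size=len(theta)), 1.0)
        theta = priors.initial_point() * jitter
        theta[6:8] = np.clip(theta[6:8], 0.0, 1.0)
        current_lp = log_post(theta, sigma0)
        tries += 1
        if tries > 1000:
            raise SamplerError("could not find a finite-posterior starting point")

    sigma_scale = 0.25 * sigma0 if sample_sigma else 0.0
    sigma = sigma0

    n_iter, n_burn = config.n_iter, config.n_burn
    dim_extra = 1 if sample_sigma else 0
    draws = np.empty((n_iter, len(PARAM_NAMES) + dim_extra))
    accepted_window = 0
    accepted_post = 0
    post_steps = 0

    chol = None  # Cholesky factor of the adapted proposal covariance
    s_global = 1.0
    n_free = int(free.sum())

    for t in range(n_iter):
        z = rng.normal(0.0, 1.0, size=len(theta))
        if chol is None:
            step = np.where(free, z * scales, 0.0)
        else:
            step = np.zeros(len(theta))
            step[free] = s_global * (chol @ z[:n_free])
        cand = theta + step
        cand_sigma = sigma
        if sample_sigma:
            cand_sigma = sigma + rng.normal(0.0, sigma_scale)
        cand_lp = log_post(cand, cand_sigma)
        if rng.random() < metropolis_acceptance(cand_lp, current_lp):
            theta, sigma, current_lp = cand, cand_sigma, cand_lp
            accepted_window += 1
            if t >= n_burn:
                accepted_post += 1
        if t >= n_burn:
            post_steps += 1
        draws[t, : len(PARAM_NAMES)] = theta
        if sample_sigma:
            draws[t, -1] = sigma

        in_burn = t < n_burn
        if in_burn and (t + 1) % config.adapt_interval == 0:
            acc = accepted_window / config.adapt_interval
            factor = float(np.clip(math.exp(acc - config.target_acceptance), 0.5, 2.0))
            if chol is None:
                scales = np.where(free, scales * factor, 0.0)
            else:
                s_global *= factor
            if sample_sigma:
                sigma_scale *= factor
            accepted_window = 0
            # covariance-shaped proposal re-estimated from the trailing half
            # of the chain through the second half of burn-in (classic
            # adaptive Metropolis), frozen at the end of burn-in so the
            # retained chain satisfies detailed balance
            if t + 1 >= n_burn // 2 and n_free > 0:
                seg = draws[(t + 1) // 2 : (t + 1), : len(PARAM_NAMES)]
                cov = np.cov(seg[:, free], rowvar=False).reshape(n_free, n_free)
                jitter = 1e-12 + 1e-6 * np.maximum(
                    priors.proposal_scales()[free], 1e-6
                ) ** 2
                cov[np.diag_indices_from(cov)] += jitter
                try:
                    new_chol = np.linalg.cholesky(cov) * (2.4 / math.sqrt(n_free))
                except np.linalg.LinAlgError:  # pragma: no cover
                    new_chol = None
                if new_chol is not None:
                    if chol is None:
                        s_global = 1.0
                    chol = new_chol

    if post_steps and accepted_post / post_steps < config.min_acceptance:
        raise SamplerError(
            "sampler stuck: post-burn-in acceptance rate "
            f"{accepted_post / post_steps:.4f} is below "
            f"{config.min_acceptance:.2f}; rescale proposals or check priors"
        )

    retained = draws[n_burn :: config.thin]
    cols = list(PARAM_NAMES) + (["sigma"] if sample_sigma else [])
    chain = pd.DataFrame(retained, columns=cols)
    chain["repair_H"] = chain["w_sldr"] * chain["repair_p"]
    chain["alpha0p_star"] = chain["alpha0p"] / chain["w_sldr"]
    chain["beta0p_star"] = chain["beta0p"] / chain["w_sldr"]

    table = pd.DataFrame(
        {"mean": chain.mean(axis=0), "sd": chain.std(axis=0, ddof=1)}
    )
    theta_mean = table.loc[list(PARAM_NAMES), "mean"].to_numpy()
    sigma_hat = float(chain["sigma"].mean()) if sample_sigma else likelihood.sigma

    r2 = {}
    preds = lik.predicted(theta_mean)
    for entry, pred in zip(lik._lines, preds):
        label = "resistant" if entry["resistant"] else "parent"
        r2[label] = r_squared(entry["obs"], pred)

    summary = PosteriorSummary(
        table=table,
        acceptance_rate=accepted_post / max(post_steps, 1),
        ess=_effective_sample_size(chain[list(PARAM_NAMES)]),
        r2=r2,
        sigma=sigma_hat,
        n_samples=len(chain),
        seed=seed,
    )
    return FamilyFit(
        chain=chain, summary=summary, priors=priors, likelihood_config=likelihood
    )
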
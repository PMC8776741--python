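"""Synthetic clonogenic-assay data with the statistical structure the fit assumes.

The generator emulates the three experimental designs used to characterize a
parental/radioresistant cell-line family:

* acute dose-response series (default doses 0-10 Gy, 1.0 Gy/min beam),
* split-dose recovery, 2 Gy + 2 Gy at intervals 0-24 h,
* multi-fractionated deliveries of 1-Gy fractions realizing reduced average
  dose rates (0.1 / 0.25 Gy/min),

plus flow-cytometry-style stem-fraction measurements.  Survival noise is
Gaussian on the -ln S scale — the same error model the fitting likelihood
uses — with observed survival capped at 1 (plating-efficiency
normalization); colony-count sampling layers are deliberately not modelled.
Default replicate count is 3 per condition and the default noise SD is 0.1
on -ln S.

All randomness flows from a single seed through ``numpy.random.SeedSequence``
spawning, so composite runs are reproducible and each sub-experiment draws
from an independent substream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import truncnorm

from .core import MicrodosimetricContext, PopulationParams, TwoPopulationModel, gamma_coefficient
from .datasets import SurvivalDataset
from .protocols import (
    AcuteDelivery,
    Delivery,
    FractionatedDelivery,
    SplitDelivery,
)
from .reference import FamilyParams, FlowCytometryObservation
from .sldr import RecoveryCurve

__all__ = [
    "ExperimentDesign",
    "DEFAULT_ACUTE_DOSES",
    "DEFAULT_SPLIT_INTERVALS",
    "DEFAULT_DOSE_RATES",
    "simulate_survival_dataset",
    "simulate_recovery_curve",
    "simulate_flow_cytometry",
    "simulate_family_bundle",
    "FamilyBundle",
]

#: Acute dose-response grid, Gy.
DEFAULT_ACUTE_DOSES = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0)
#: Split-dose inter-fraction intervals, h.
DEFAULT_SPLIT_INTERVALS = (0.0, 0.5, 1.0, 2.0, 3.0, 6.0, 12.0, 24.0)
#: Average dose rates for the fractionated series, Gy/min.
DEFAULT_DOSE_RATES = (0.01, 0.05, 0.1, 0.25, 1.0)


@dataclass(frozen=True)
class ExperimentDesign:
    """Design of one simulated survival experiment.

    ``kind`` selects the delivery: "acute" (instantaneous), "split"
    (2-fraction, using ``split_interval_h``), or "fractionated" (1-Gy
    fractions at ``beam_rate_gy_min`` spaced to an ``average_rate_gy_min``).
    ``sigma`` is the Gaussian noise SD on -ln S.
    """

    doses: tuple[float, ...] = DEFAULT_ACUTE_DOSES
    kind: str = "acute"
    split_interval_h: float = 3.0
    fraction_size: float = 1.0
    beam_rate_gy_min: float = 1.0
    average_rate_gy_min: float = 0.1
    replicates: int = 3
    sigma: float = 0.1

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.kind not in ("acute", "split", "fractionated"):
            raise ValueError(f"unknown design kind {self.kind!r}")
        if self.average_rate_gy_min > self.beam_rate_gy_min:
            raise ValueError("average dose rate cannot exceed the beam rate")

    def delivery(self) -> Delivery:
        if self.kind == "acute":
            return AcuteDelivery()
        if self.kind == "split":
            return SplitDelivery(tau_h=self.split_interval_h)
        return FractionatedDelivery(
            fraction_size=self.fraction_size,
            beam_rate_gy_min=self.beam_rate_gy_min,
            average_rate_gy_min=self.average_rate_gy_min,
        )

    @property
    def protocol_id(self) -> str:
        if self.kind == "acute":
            return "acute"
        if self.kind == "split":
            return f"split_{self.split_interval_h}h"
        return f"fractionated_{self.average_rate_gy_min}GyMin"


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_survival_dataset(
    model: TwoPopulationModel,
    ctx: MicrodosimetricContext,
    design: ExperimentDesign,
    seed=None,
    cell_line: str = "synthetic",
) -> SurvivalDataset:
    """Noisy clonogenic observations of one line under one design.

    For every dose x replicate, ``-ln S_obs = -ln S_model + eps`` with
    ``eps ~ Normal(0, sigma^2)``, clipped below at 0 so that observed
    survival never exceeds 1 (the plating-efficiency normalization bound).
    The generating model parameters are recorded in ``dataset.meta`` for
    parameter-recovery tests.
    """
    rng = _rng(seed)
    delivery = design.delivery()
    gamma = gamma_coefficient(ctx)
    prog = model.effective_progeny
    doses, truths = [], []
    for D in design.doses:
        Sp = np.exp(-delivery.neg_log_survival(prog, gamma, D))
        Ss = np.exp(-delivery.neg_log_survival(model.stem, gamma, D))
        S = (1.0 - model.f_s) * Sp + model.f_s * Ss
        doses.extend([D] * design.replicates)
        truths.extend([-np.log(S)] * design.replicates)
    truths = np.asarray(truths)
    noise = rng.normal(0.0, design.sigma, size=len(truths)) if design.sigma else 0.0
    observed = np.maximum(truths + noise, 0.0)
    replicate = np.tile(np.arange(design.replicates), len(design.doses))
    meta = {
        "cell_line": cell_line,
        "design": design,
        "sigma": design.sigma,
        "truth_neg_log_S": truths,
        "truth_model": model,
    }
    return SurvivalDataset.from_observations(
        cell_line,
        doses,
        observed,
        replicate=replicate,
        protocol_id=design.protocol_id,
        meta=meta,
    )


def simulate_recovery_curve(
    pop: PopulationParams,
    gamma: float,
    D1: float = 2.0,
    D2: float = 2.0,
    intervals: Sequence[float] = DEFAULT_SPLIT_INTERVALS,
    sigma: float = 0.05,
    replicates: int = 3,
    seed=None,
) -> RecoveryCurve:
    """Split-dose recovery curve of a single population with -ln S noise."""
    from .core import neg_log_survival_split

    rng = _rng(seed)
    intervals = np.asarray(list(intervals), dtype=float)
    if not np.any(intervals == 0.0) or intervals.max() < 6.0:
        raise ValueError(
            "intervals must include 0 h and extend to >= 6 h to bracket "
            "the recovery curve"
        )
    tau = np.repeat(intervals, replicates)
    y = np.array(
        [neg_log_survival_split(pop, gamma, D1, D2, t) for t in tau]
    )
    if sigma:
        y = np.maximum(y + rng.normal(0.0, sigma, size=len(y)), 0.0)
    replicate = np.tile(np.arange(replicates), len(intervals))
    return RecoveryCurve(tau, np.exp(-y), (D1, D2), replicate)


def simulate_flow_cytometry(
    f_s_true: float,
    sd: float,
    n_experiments: int = 3,
    seed=None,
) -> FlowCytometryObservation:
    """Repeated stem-fraction measurements: truncated-normal draws in [0, 1].

    Returns the sample mean/SD/count, the summary used as an f_s prior.
    With ``sd=0`` the observation is exact.
    """
    if not 0.0 <= f_s_true <= 1.0:
        raise ValueError("f_s_true must lie in [0, 1]")
    if n_experiments < 2:
        raise ValueError("need >= 2 experiments to report an SD")
    if sd == 0:
        return FlowCytometryObservation(f_s_true, 0.0, n_experiments)
    rng = _rng(seed)
    a, b = (0.0 - f_s_true) / sd, (1.0 - f_s_true) / sd
    draws = truncnorm.rvs(a, b, loc=f_s_true, scale=sd, size=n_experiments,
                          random_state=rng)
    return FlowCytometryObservation(
        float(np.mean(draws)), float(np.std(draws, ddof=1)), n_experiments
    )


@dataclass(frozen=True)
class FamilyBundle:
    """Everything the two-stage analysis of one family consumes.

    Parent-line recovery curve, flow-cytometry summaries for both lines,
    acute survival datasets for both lines, and the generating truth.
    """

    truth: FamilyParams
    recovery: RecoveryCurve
    flow_parent: FlowCytometryObservation
    flow_resistant: FlowCytometryObservation
    parent_survival: SurvivalDataset
    resistant_survival: SurvivalDataset
    seed: int | None


def simulate_family_bundle(
    truth: FamilyParams,
    ctx: MicrodosimetricContext,
    seed: int | None = None,
    design: ExperimentDesign | None = None,
    flow_sd_parent: float = 0.0068,
    flow_sd_resistant: float = 0.0365,
    recovery_sigma: float = 0.05,
) -> FamilyBundle:
    """Simulate the full experimental campaign for one cell-line family.

    One seed fans out into four independent substreams (recovery, flow
    parent, flow resistant, survival) via ``SeedSequence.spawn``; the
    default flow-measurement SDs are typical ALDEFLUOR replicate spreads
    for a low-f_s parent and a ~10x enriched resistant line.
    """
    design = design or ExperimentDesign()
    streams = np.random.SeedSequence(seed).spawn(5)
    rngs = [np.random.default_rng(s) for s in streams]
    gamma = gamma_coefficient(ctx)
    parent_model = truth.parent_model()
    resistant_model = truth.resistant_model()

    recovery = simulate_recovery_curve(
        parent_model.progeny,
        gamma,
        sigma=recovery_sigma,
        replicates=design.replicates,
        seed=rngs[0],
    )
    flow_parent = simulate_flow_cytometry(
        truth.f_s_parent, flow_sd_parent, seed=rngs[1]
    )
    flow_resistant = simulate_flow_cytometry(
        truth.f_s_resistant, flow_sd_resistant, seed=rngs[2]
    )
    parent_survival = simulate_survival_dataset(
        parent_model, ctx, design, seed=rngs[3], cell_line=f"{truth.name}"
    )
    resistant_survival = simulate_survival_dataset(
        resistant_model, ctx, design, seed=rngs[4], cell_line=f"{truth.name}-R"
    )
    return FamilyBundle(
        truth=truth,
        recovery=recovery,
        flow_parent=flow_parent,
        flow_resistant=flow_resistant,
        parent_survival=parent_survival,
        resistant_survival=resistant_survival,
        seed=seed,
    )
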
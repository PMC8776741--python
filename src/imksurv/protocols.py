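"""Irradiation protocols: timed fraction sequences and their IMK evaluation.

A protocol is an ordered sequence of dose fractions, each with a start time,
an absorbed dose and a beam-on duration (all in h and Gy).  The lethal-lesion
burden generalizes the two-fraction split-dose form to n fractions: each
fraction contributes its own LQ term with a per-fraction Lea-Catcheside
factor, and every ordered pair (i, j) contributes a sub-lethal damage cross
term damped over the end-of-i to start-of-j gap::

    -ln S = sum_i [(alpha0 + gamma beta0) D_i + F_i beta0 D_i^2]
            + 2 beta0 sum_{i<j} exp(-(a+c) tau_ij) D_i D_j

This reduces exactly to the split-dose form for two instantaneous fractions
and to the continuous single-dose form for one fraction, and its
many-small-fraction limit converges to the Lea-Catcheside integral.

Delivery templates (`AcuteDelivery`, `SplitDelivery`, `FractionatedDelivery`)
map a total dose to a concrete protocol so that dose-response curves for a
whole experimental arm can be computed from one description.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    MicrodosimetricContext,
    PopulationParams,
    TwoPopulationModel,
    gamma_coefficient,
    mixture_survival,
    neg_log_survival_single,
)
from .exceptions import InvalidProtocolError

__all__ = [
    "Fraction",
    "IrradiationProtocol",
    "neg_log_survival_protocol",
    "make_fractionation_protocol",
    "Delivery",
    "AcuteDelivery",
    "SplitDelivery",
    "FractionatedDelivery",
    "survival_curve",
]


@dataclass(frozen=True)
class Fraction:
    """One dose fraction: dose (Gy), start time and beam-on duration (h)."""

    dose: float
    start_time: float = 0.0
    duration: float = 0.0

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError(f"fraction dose must be non-negative, got {self.dose}")
        if self.duration < 0:
            raise ValueError(
                f"fraction duration must be non-negative, got {self.duration}"
            )

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration


@dataclass(frozen=True)
class IrradiationProtocol:
    """Ordered, non-overlapping sequence of dose fractions."""

    fractions: tuple[Fraction, ...]

    def __init__(self, fractions: Iterable[Fraction]):
        fracs = tuple(
            f if isinstance(f, Fraction) else Fraction(*f) for f in fractions
        )
        if not fracs:
            raise InvalidProtocolError("protocol must contain at least one fraction")
        for a, b in zip(fracs, fracs[1:]):
            if not b.start_time > a.start_time:
                raise InvalidProtocolError(
                    "fraction start times must be strictly increasing "
                    f"({a.start_time} h then {b.start_time} h)"
                )
            if b.start_time < a.end_time - 1e-12:
                raise InvalidProtocolError(
                    f"fractions overlap: one ends at {a.end_time} h, "
                    f"next starts at {b.start_time} h"
                )
        object.__setattr__(self, "fractions", fracs)

    @property
    def total_dose(self) -> float:
        return sum(f.dose for f in self.fractions)

    @property
    def elapsed_time(self) -> float:
        """Start of first fraction to end of last, in h."""
        return self.fractions[-1].end_time - self.fractions[0].start_time

    @classmethod
    def single(cls, dose: float, duration: float = 0.0) -> "IrradiationProtocol":
        return cls([Fraction(dose, 0.0, duration)])

    @classmethod
    def split(cls, D1: float, D2: float, tau: float) -> "IrradiationProtocol":
        """Two instantaneous fractions separated by tau (h)."""
        return cls([Fraction(D1, 0.0, 0.0), Fraction(D2, tau, 0.0)])


def neg_log_survival_protocol(
    pop: PopulationParams, gamma: float, protocol: IrradiationProtocol
) -> float:
    """-ln S of one population after an arbitrary fractionation protocol.

    Per-fraction LQ terms use the Lea-Catcheside factor of each fraction's
    own duration; pairwise cross terms decay over the gap from the end of the
    earlier fraction to the start of the later one.
    """
    fracs = protocol.fractions
    total = 0.0
    for f in fracs:
        total += neg_log_survival_single(pop, gamma, f.dose, f.duration)
    k = pop.repair_rate
    cross = 0.0
    for i, fi in enumerate(fracs):
        for fj in fracs[i + 1 :]:
            tau = max(fj.start_time - fi.end_time, 0.0)
            cross += math.exp(-k * tau) * fi.dose * fj.dose
    return total + 2.0 * pop.beta0 * cross


def make_fractionation_protocol(
    total_dose: float,
    fraction_size: float,
    beam_rate_gy_min: float,
    average_rate_gy_min: float,
) -> IrradiationProtocol:
    """Equal fractions with equal gaps realizing a prescribed average dose rate.

    ``n = total_dose / fraction_size`` fractions, each delivered at the beam
    dose rate, are spaced so that the total elapsed time equals
    ``total_dose / average_rate``.  E.g. 10 Gy in 1-Gy fractions at a 1.0
    Gy/min beam with a 0.1 Gy/min average rate gives 10 fractions over
    100 min with 10-min gaps.

    Dose rates are accepted in Gy/min (the usual experimental unit) and
    converted to Gy/h internally.
    """
    if not total_dose > 0 or not fraction_size > 0:
        raise ValueError("total_dose and fraction_size must be positive")
    n_float = total_dose / fraction_size
    n = round(n_float)
    if n < 1 or abs(n_float - n) > 1e-9 * max(1.0, n_float):
        raise ValueError(
            f"total_dose {total_dose} Gy is not a whole number of "
            f"{fraction_size} Gy fractions"
        )
    if average_rate_gy_min > beam_rate_gy_min + 1e-12:
        raise InvalidProtocolError(
            f"average dose rate ({average_rate_gy_min} Gy/min) cannot exceed "
            f"the beam dose rate ({beam_rate_gy_min} Gy/min)"
        )
    duration = fraction_size / (beam_rate_gy_min * 60.0)  # h
    elapsed = total_dose / (average_rate_gy_min * 60.0)  # h
    gap = 0.0 if n == 1 else (elapsed - n * duration) / (n - 1)
    if gap < -1e-12:
        raise InvalidProtocolError("requested timing is infeasible")
    gap = max(gap, 0.0)
    fracs = [
        Fraction(fraction_size, i * (duration + gap), duration) for i in range(n)
    ]
    return IrradiationProtocol(fracs)


class Delivery:
    """Template mapping a total dose to a concrete irradiation protocol."""

    def protocol(self, dose: float) -> IrradiationProtocol:  # pragma: no cover
        raise NotImplementedError

    def neg_log_survival(
        self, pop: PopulationParams, gamma: float, dose: float
    ) -> float:
        if dose == 0.0:
            return 0.0
        return neg_log_survival_protocol(pop, gamma, self.protocol(dose))


@dataclass(frozen=True)
class AcuteDelivery(Delivery):
    """Single continuous exposure; ``dose_rate_gy_min=None`` means instantaneous."""

    dose_rate_gy_min: float | None = None

    def protocol(self, dose: float) -> IrradiationProtocol:
        T = 0.0 if self.dose_rate_gy_min is None else dose / (
            self.dose_rate_gy_min * 60.0
        )
        return IrradiationProtocol.single(dose, T)

    def neg_log_survival(
        self, pop: PopulationParams, gamma: float, dose: float
    ) -> float:
        T = 0.0 if self.dose_rate_gy_min is None else dose / (
            self.dose_rate_gy_min * 60.0
        )
        return neg_log_survival_single(pop, gamma, dose, T)


@dataclass(frozen=True)
class SplitDelivery(Delivery):
    """Total dose split into two acute fractions separated by ``tau_h`` hours."""

    tau_h: float
    first_fraction: float = 0.5  # share of the total dose in fraction 1

    def protocol(self, dose: float) -> IrradiationProtocol:
        D1 = self.first_fraction * dose
        return IrradiationProtocol.split(D1, dose - D1, self.tau_h)


@dataclass(frozen=True)
class FractionatedDelivery(Delivery):
    """Multi-fraction delivery achieving a reduced average dose rate."""

    fraction_size: float = 1.0
    beam_rate_gy_min: float = 1.0
    average_rate_gy_min: float = 0.1

    def protocol(self, dose: float) -> IrradiationProtocol:
        return make_fractionation_protocol(
            dose, self.fraction_size, self.beam_rate_gy_min, self.average_rate_gy_min
        )


def survival_curve(
    model: TwoPopulationModel,
    ctx: MicrodosimetricContext,
    doses: Sequence[float],
    delivery: Delivery | None = None,
) -> pd.DataFrame:
    """Predicted mixture survival over a dose grid for one delivery template.

    Returns a DataFrame with columns ``dose_Gy``, ``surviving_fraction`` and
    ``neg_log_S``.  The log-survival of the mixture flattens toward the more
    resistant (stem-like) component at high dose, producing the sigmoid shape
    characteristic of heterogeneous populations.
    """
    delivery = delivery or AcuteDelivery()
    doses = np.asarray(list(doses), dtype=float)
    if np.any(doses < 0):
        raise ValueError("doses must be non-negative")
    S = np.empty_like(doses)
    gamma = gamma_coefficient(ctx)
    prog = model.effective_progeny
    for idx, D in enumerate(doses):
        Sp = math.exp(-delivery.neg_log_survival(prog, gamma, D))
        Ss = math.exp(-delivery.neg_log_survival(model.stem, gamma, D))
        S[idx] = mixture_survival(Sp, Ss, model.f_s)
    with np.errstate(divide="ignore"):
        neg_log = -np.log(S)
    return pd.DataFrame(
        {"dose_Gy": doses, "surviving_fraction": S, "neg_log_S": neg_log}
    )
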
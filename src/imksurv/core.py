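"""Closed-form IMK (integrated microdosimetric-kinetic) surviving fractions.

The IMK model describes clonogenic survival of a cell population exposed to
ionizing radiation.  The nucleus is treated as a collection of micron-scale
domains; potentially lethal lesions (PLLs) created in a domain either become
lethal (rate ``a``), pairwise interact to lethality (rate ``b_d``) or are
repaired (rate ``c``).  Only the sum ``a + c`` — the sub-lethal damage repair
(SLDR) rate — appears in the closed forms, together with linear-quadratic
lethality coefficients ``alpha0`` (Gy^-1) and ``beta0`` (Gy^-2).

For a single population receiving dose ``D`` over delivery time ``T``::

    -ln S = (alpha0 + gamma * beta0) * D + F * beta0 * D**2

where ``gamma = y_D / (rho * pi * r_d**2)`` is the mean dose per domain per
event (Gy) and ``F`` is the Lea-Catcheside protraction factor.  Split-dose
and multi-fraction protocols add pairwise cross terms damped by
``exp(-(a + c) * tau)`` over the inter-fraction interval ``tau``.

A cell line is modelled as a mixture of progeny cells and a radioresistant
stem-like (CSC) sub-population; the observable survival is the
fraction-weighted sum of the two component survivals.

All rates are in h^-1, times in h, doses in Gy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import InvalidContextError

__all__ = [
    "KEV_TO_JOULE",
    "MicrodosimetricContext",
    "PopulationParams",
    "TwoPopulationModel",
    "gamma_coefficient",
    "lea_catcheside_factor",
    "neg_log_survival_single",
    "neg_log_survival_split",
    "derive_resistant_progeny",
    "mixture_survival",
]

#: CODATA exact conversion, J per keV.
KEV_TO_JOULE = 1.602176634e-16


@dataclass(frozen=True)
class MicrodosimetricContext:
    """Track-structure constants defining the per-domain dose coefficient.

    Parameters
    ----------
    y_D : float
        Dose-mean lineal energy in keV/um, a microdosimetric descriptor of
        the radiation quality (4.68 keV/um for the 150 kVp X rays used for
        the reference datasets).
    rho : float
        Density of the domain medium in g/cm^3 (liquid water: 1.0).
    r_d : float
        Domain radius in um (default 0.5, i.e. 1 um diameter domains).
    """

    y_D: float = 4.68
    rho: float = 1.0
    r_d: float = 0.5

    def __post_init__(self) -> None:
        for name in ("y_D", "rho", "r_d"):
            if not getattr(self, name) > 0:
                raise InvalidContextError(
                    f"MicrodosimetricContext.{name} must be strictly positive, "
                    f"got {getattr(self, name)!r}"
                )

    @property
    def gamma(self) -> float:
        """Per-domain dose coefficient (Gy); see :func:`gamma_coefficient`."""
        return gamma_coefficient(self)


def gamma_coefficient(ctx: MicrodosimetricContext) -> float:
    """Mean dose deposited per event in one domain, ``y_D/(rho*pi*r_d^2)``, in Gy.

    The lineal energy ``y_D`` (keV/um) divided by the mass per unit chord
    length of a domain gives an energy per mass.  With ``rho`` in g/cm^3
    (= 1e-12 g/um^3) and ``r_d`` in um the conversion to Gy (J/kg) is::

        gamma = y_D [keV/um] * 1.602176634e-16 [J/keV]
                / (rho * 1e-12 [g/um^3] * pi * r_d^2 [um^2]) * 1e3 [g/kg]

    For y_D = 4.68 keV/um, rho = 1 g/cm^3, r_d = 0.5 um this is 0.9547 Gy.
    """
    if not isinstance(ctx, MicrodosimetricContext):
        ctx = MicrodosimetricContext(*ctx)
    return ctx.y_D * KEV_TO_JOULE / (ctx.rho * 1e-12 * math.pi * ctx.r_d**2) * 1e3


@dataclass(frozen=True)
class PopulationParams:
    """LQ coefficients and SLDR rate for one homogeneous cell population.

    ``alpha0`` (Gy^-1) and ``beta0`` (Gy^-2) are the first- and second-order
    lethality coefficients; ``repair_rate`` is the SLDR rate ``a + c`` in
    h^-1 (literature range for carcinoma lines roughly 1.5-2.2 h^-1).
    """

    alpha0: float
    beta0: float
    repair_rate: float

    def __post_init__(self) -> None:
        if self.alpha0 < 0 or self.beta0 < 0:
            raise ValueError(
                f"alpha0 and beta0 must be non-negative, got "
                f"({self.alpha0}, {self.beta0})"
            )
        if not self.repair_rate > 0:
            raise ValueError(f"repair_rate must be positive, got {self.repair_rate}")


def lea_catcheside_factor(repair_rate: float, T: float) -> float:
    """Lea-Catcheside protraction factor F for a uniform delivery of length T.

    ::

        F = 2 / ((a+c)^2 T^2) * [(a+c) T + exp(-(a+c) T) - 1]

    F is 1 for an acute exposure (T = 0, evaluated by series expansion for
    ``(a+c) T < 1e-6``), decreases strictly with T, and behaves as
    ``2/((a+c) T)`` for very long deliveries, suppressing the quadratic
    (lesion-interaction) term of the LQ form.

    Parameters
    ----------
    repair_rate : float
        SLDR rate ``a + c`` in h^-1; must be positive.
    T : float
        Delivery (beam-on) time in h; must be non-negative.
    """
    if not repair_rate > 0:
        raise ValueError(f"repair_rate must be positive, got {repair_rate}")
    if T < 0:
        raise ValueError(f"delivery time must be non-negative, got {T}")
    x = repair_rate * T
    if x < 1e-6:
        # second-order series of 2/x^2 (x + e^-x - 1) around x = 0
        return 1.0 - x / 3.0 + x * x / 12.0
    # expm1 keeps x + (e^-x - 1) accurate where the naive form cancels
    return 2.0 / (x * x) * (x + math.expm1(-x))


def neg_log_survival_single(
    pop: PopulationParams, gamma: float, dose: float, T: float = 0.0
) -> float:
    """Lethal-lesion burden -ln S after one dose delivered over time T.

    ``(alpha0 + gamma*beta0)*D + F*beta0*D^2`` with F the protraction factor
    for ``pop.repair_rate`` and delivery time T.  Returns 0 at zero dose.
    """
    if dose < 0:
        raise ValueError(f"dose must be non-negative, got {dose}")
    F = lea_catcheside_factor(pop.repair_rate, T)
    return (pop.alpha0 + gamma * pop.beta0) * dose + F * pop.beta0 * dose**2


def neg_log_survival_split(
    pop: PopulationParams,
    gamma: float,
    D1: float,
    D2: float,
    tau: float,
) -> float:
    """-ln S for two acute fractions D1, D2 separated by interval tau (h).

    ::

        sum_i [(alpha0 + gamma*beta0) D_i + beta0 D_i^2]
            + 2 beta0 exp(-(a+c) tau) D1 D2

    At tau = 0 this equals the acute single-dose form at D1 + D2; as
    tau -> inf the cross term vanishes and the fractions act independently.
    """
    if D1 < 0 or D2 < 0:
        raise ValueError(f"doses must be non-negative, got ({D1}, {D2})")
    if tau < 0:
        raise ValueError(f"inter-fraction interval must be non-negative, got {tau}")
    base = sum(
        (pop.alpha0 + gamma * pop.beta0) * D + pop.beta0 * D**2 for D in (D1, D2)
    )
    cross = 2.0 * pop.beta0 * math.exp(-pop.repair_rate * tau) * D1 * D2
    return base + cross


def derive_resistant_progeny(parent: PopulationParams, w_sldr: float) -> PopulationParams:
    """Progeny-cell parameters after SLDR enhancement by the factor w_SLDR.

    Radioresistant sub-lines carry progeny cells whose SLDR rate is enhanced
    to ``w_SLDR * (a+c)_p``; since alpha0 and beta0 are inversely
    proportional to the repair rate, both are divided by the same factor::

        alpha0* = alpha0 / w_SLDR
        beta0*  = beta0 / w_SLDR
        (a+c)*  = w_SLDR * (a+c)

    ``w_SLDR = 1`` returns the parent unchanged (non-radioresistant case).
    """
    if not w_sldr > 0:
        raise ValueError(f"w_sldr must be positive, got {w_sldr}")
    if w_sldr == 1.0:
        return parent
    return PopulationParams(
        alpha0=parent.alpha0 / w_sldr,
        beta0=parent.beta0 / w_sldr,
        repair_rate=w_sldr * parent.repair_rate,
    )


def mixture_survival(S_p: float, S_s: float, f_s: float) -> float:
    """Overall survival of a progeny/stem mixture: ``(1-f_s) S_p + f_s S_s``.

    ``f_s`` is the stem-like (CSC) fraction; the progeny fraction is always
    ``1 - f_s``.
    """
    if not 0.0 <= f_s <= 1.0:
        raise ValueError(f"f_s must lie in [0, 1], got {f_s}")
    Sp = np.asarray(S_p, dtype=float)
    Ss = np.asarray(S_s, dtype=float)
    if np.any(Sp < 0) or np.any(Sp > 1) or np.any(Ss < 0) or np.any(Ss > 1):
        raise ValueError("component survivals must lie in [0, 1]")
    out = (1.0 - f_s) * Sp + f_s * Ss
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class TwoPopulationModel:
    """Progeny + stem-like mixture model for one cell line.

    Parameters
    ----------
    progeny : PopulationParams
        Parameters of the *parental* progeny population (``alpha0p``,
        ``beta0p``, ``(a+c)_p``).  For a radioresistant line the effective
        progeny parameters are derived from these via ``w_sldr``
        (:func:`derive_resistant_progeny`); they are never stored separately.
    stem : PopulationParams
        Stem-like (CSC) population.  Its repair rate ``(a+c)_H`` is
        structurally tied to ``w_sldr * progeny.repair_rate`` and is checked
        at construction; use :meth:`build` to have it derived for you.
    f_s : float
        Stem-like fraction of this line, in [0, 1].  The progeny fraction is
        represented as ``1 - f_s``.
    w_sldr : float
        Ratio of the stem/enhanced repair rate to the parental progeny rate
        (dimensionless, >= 1 for the default prior).
    radioresistant : bool
        If True the line's progeny cells carry the enhanced SLDR rate, i.e.
        effective progeny parameters are ``(alpha0p/w, beta0p/w, w*(a+c)_p)``.
    """

    progeny: PopulationParams
    stem: PopulationParams
    f_s: float
    w_sldr: float = 1.0
    radioresistant: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_s <= 1.0:
            raise ValueError(f"f_s must lie in [0, 1], got {self.f_s}")
        if not self.w_sldr > 0:
            raise ValueError(f"w_sldr must be positive, got {self.w_sldr}")
        expected = self.w_sldr * self.progeny.repair_rate
        if not math.isclose(self.stem.repair_rate, expected, rel_tol=1e-9):
            raise ValueError(
                "stem repair rate must equal w_sldr * parental progeny repair "
                f"rate ({expected:.6g} h^-1), got {self.stem.repair_rate:.6g}"
            )

    @classmethod
    def build(
        cls,
        *,
        alpha0p: float,
        beta0p: float,
        repair_p: float,
        alpha0s: float,
        beta0s: float,
        w_sldr: float = 1.0,
        f_s: float = 0.0,
        radioresistant: bool = False,
    ) -> "TwoPopulationModel":
        """Construct from scalar family parameters, deriving ``(a+c)_H``."""
        progeny = PopulationParams(alpha0p, beta0p, repair_p)
        stem = PopulationParams(alpha0s, beta0s, w_sldr * repair_p)
        return cls(progeny, stem, f_s=f_s, w_sldr=w_sldr, radioresistant=radioresistant)

    @property
    def effective_progeny(self) -> PopulationParams:
        """Progeny parameters actually governing this line's progeny survival."""
        if self.radioresistant:
            return derive_resistant_progeny(self.progeny, self.w_sldr)
        return self.progeny

    def resistant_sibling(self, f_s: float) -> "TwoPopulationModel":
        """The radioresistant line of the same family with stem fraction f_s."""
        return replace(self, f_s=f_s, radioresistant=True)

    def survival(
        self, ctx: MicrodosimetricContext, dose: float, T: float = 0.0
    ) -> float:
        """Mixture survival after a single dose delivered over time T (h)."""
        gamma = gamma_coefficient(ctx)
        S_p = math.exp(-neg_log_survival_single(self.effective_progeny, gamma, dose, T))
        S_s = math.exp(-neg_log_survival_single(self.stem, gamma, dose, T))
        return mixture_survival(S_p, S_s, self.f_s)

    def survival_split(
        self, ctx: MicrodosimetricContext, D1: float, D2: float, tau: float
    ) -> float:
        """Mixture survival after two acute fractions separated by tau (h)."""
        gamma = gamma_coefficient(ctx)
        S_p = math.exp(
            -neg_log_survival_split(self.effective_progeny, gamma, D1, D2, tau)
        )
        S_s = math.exp(-neg_log_survival_split(self.stem, gamma, D1, D2, tau))
        return mixture_survival(S_p, S_s, self.f_s)
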
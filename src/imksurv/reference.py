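"""Reference parameter sets for the SAS and HSC2 oral squamous carcinoma families.

Each family pairs a non-radioresistant parental line (SAS, HSC2) with a
radioresistant sub-line (SAS-R, HSC2-R) established by prolonged fractionated
X-ray exposure.  The values below are the published IMK estimates for 150 kVp
X rays (y_D = 4.68 keV/um, 0.5-um domains): parental progeny LQ coefficients
and SLDR rate, shared stem-like (CSC) coefficients, the SLDR enhancement
ratio w_SLDR of the resistant line, and the stem fractions of both lines.

They serve as defaults for worked examples and as ground truth for the
synthetic-data generator and parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import MicrodosimetricContext, TwoPopulationModel

__all__ = [
    "FamilyParams",
    "FlowCytometryObservation",
    "SAS_FAMILY",
    "HSC2_FAMILY",
    "REFERENCE_CONTEXT",
    "ALDH_FRACTIONS",
]

#: 150 kVp X-ray track structure in liquid water, 0.5-um domains (gamma = 0.954 Gy).
REFERENCE_CONTEXT = MicrodosimetricContext(y_D=4.68, rho=1.0, r_d=0.5)


@dataclass(frozen=True)
class FamilyParams:
    """Joint parameters of a parental + radioresistant cell-line pair."""

    name: str
    alpha0p: float  # Gy^-1, parental progeny
    beta0p: float  # Gy^-2, parental progeny
    repair_p: float  # h^-1, parental progeny SLDR rate (a+c)_p
    alpha0s: float  # Gy^-1, stem-like cells (shared across the family)
    beta0s: float  # Gy^-2, stem-like cells
    w_sldr: float  # dimensionless SLDR enhancement of the resistant line
    f_s_parent: float  # stem fraction of the parental line
    f_s_resistant: float  # stem fraction of the resistant line

    def parent_model(self) -> TwoPopulationModel:
        """Mixture model of the non-radioresistant parental line."""
        return TwoPopulationModel.build(
            alpha0p=self.alpha0p,
            beta0p=self.beta0p,
            repair_p=self.repair_p,
            alpha0s=self.alpha0s,
            beta0s=self.beta0s,
            w_sldr=self.w_sldr,
            f_s=self.f_s_parent,
            radioresistant=False,
        )

    def resistant_model(self) -> TwoPopulationModel:
        """Mixture model of the radioresistant sub-line."""
        return TwoPopulationModel.build(
            alpha0p=self.alpha0p,
            beta0p=self.beta0p,
            repair_p=self.repair_p,
            alpha0s=self.alpha0s,
            beta0s=self.beta0s,
            w_sldr=self.w_sldr,
            f_s=self.f_s_resistant,
            radioresistant=True,
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "alpha0p": self.alpha0p,
            "beta0p": self.beta0p,
            "repair_p": self.repair_p,
            "alpha0s": self.alpha0s,
            "beta0s": self.beta0s,
            "w_sldr": self.w_sldr,
            "f_s_parent": self.f_s_parent,
            "f_s_resistant": self.f_s_resistant,
        }


SAS_FAMILY = FamilyParams(
    name="SAS",
    alpha0p=0.208,
    beta0p=0.044,
    repair_p=1.279,
    alpha0s=0.074,
    beta0s=0.027,
    w_sldr=1.059,
    f_s_parent=0.012,
    f_s_resistant=0.083,
)

HSC2_FAMILY = FamilyParams(
    name="HSC2",
    alpha0p=0.166,
    beta0p=0.168,
    repair_p=1.499,
    alpha0s=0.194,
    beta0s=0.019,
    w_sldr=1.896,
    f_s_parent=0.014,
    f_s_resistant=0.127,
)


@dataclass(frozen=True)
class FlowCytometryObservation:
    """Summary of repeated ALDH(+) fraction measurements: mean, SD, count."""

    mean: float
    sd: float
    n: int


#: ALDEFLUOR flow-cytometry ALDH(+) fractions (mean +/- SD over 3 runs).
ALDH_FRACTIONS = {
    "SAS": FlowCytometryObservation(0.0097, 0.0068, 3),
    "SAS-R": FlowCytometryObservation(0.0965, 0.0365, 3),
    "HSC2": FlowCytometryObservation(0.0136, 0.0032, 3),
    "HSC2-R": FlowCytometryObservation(0.1261, 0.0611, 3),
}
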
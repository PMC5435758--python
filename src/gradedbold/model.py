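"""Forward biophysical model of the calibrated-BOLD experiment.

The BOLD signal change produced by a vasoactive stimulus is modelled with the
Davis equation,

    dBOLD/BOLD0 = M * [1 - (CBF/CBF0)**(alpha - beta) * (CMRO2/CMRO2_0)**beta],

where ``M`` is the calibration parameter (the ceiling BOLD change were all
deoxyhaemoglobin removed), ``alpha`` couples blood volume to blood flow and
``beta`` relates venous deoxyhaemoglobin to the transverse relaxation rate.

Hypercapnia is classically assumed iso-metabolic (CMRO2 ratio of 1).  Here the
basal CMRO2 response is instead parameterised linearly in the end-tidal CO2
rise,

    CMRO2/CMRO2_0 = 1 + kappa * dPETCO2,

with ``kappa`` the fractional CMRO2 change per mmHg.  Substituting the dose
model into the Davis equation gives the graded forward model used by the
fitting layer.

All quantities in this module are dimensionless fractions (not percent) and
ratios; unit conversion to the percent scale happens only at I/O boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "AlphaBetaPairing",
    "PAIRINGS",
    "get_pairing",
    "cmro2_ratio_from_dose",
    "davis_bold",
    "graded_bold",
    "invert_for_cmro2",
    "relative_bold_contrast",
]


@dataclass(frozen=True)
class AlphaBetaPairing:
    """One of the calibrated-BOLD exponent conventions.

    Parameters
    ----------
    name : str
        Label for the convention ("empirical", "3T", "simplified", or a
        custom label).
    alpha : float
        Flow-volume coupling exponent, ``0 < alpha < 1``.
    beta : float
        Deoxyhaemoglobin-relaxation exponent, ``0 < beta <= 2``.
    """

    name: str
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0.0 < self.beta <= 2.0:
            raise ValueError(f"beta must lie in (0, 2], got {self.beta}")


#: The three conventions in common use at 3 T.  "simplified" is the
#: single-parameter theta = 0.06 model written in alpha/beta form.
PAIRINGS: dict[str, AlphaBetaPairing] = {
    "empirical": AlphaBetaPairing("empirical", 0.14, 0.91),
    "3T": AlphaBetaPairing("3T", 0.2, 1.3),
    "simplified": AlphaBetaPairing("simplified", 0.06, 1.0),
}


def get_pairing(pairing: "AlphaBetaPairing | str") -> AlphaBetaPairing:
    """Resolve a pairing given by name or pass one through unchanged."""
    if isinstance(pairing, AlphaBetaPairing):
        return pairing
    try:
        return PAIRINGS[pairing]
    except KeyError:
        raise KeyError(
            f"unknown pairing {pairing!r}; choose from {sorted(PAIRINGS)} "
            "or pass an AlphaBetaPairing"
        ) from None


def cmro2_ratio_from_dose(kappa: float, delta_petco2: float) -> float:
    """CMRO2 ratio implied by the linear dose model, ``1 + kappa * dPETCO2``.

    Parameters
    ----------
    kappa : float
        Fractional basal CMRO2 change per mmHg end-tidal CO2 rise.
    delta_petco2 : float
        End-tidal CO2 rise above normocapnia, mmHg.

    Returns
    -------
    float
        ``CMRO2_HC / CMRO2_0``; raises ``ValueError`` if the linear model
        would drive the ratio to zero or below.
    """
    ratio = 1.0 + kappa * delta_petco2
    if ratio <= 0.0:
        raise ValueError(
            "CMRO2 ratio must stay positive; "
            f"kappa={kappa}, delta_petco2={delta_petco2} gives {ratio}"
        )
    return ratio


def davis_bold(
    m: float,
    cbf_ratio: float,
    cmro2_ratio: float,
    pairing: "AlphaBetaPairing | str" = "empirical",
) -> float:
    """Fractional BOLD change predicted by the Davis model.

    ``m * (1 - cbf_ratio**(alpha-beta) * cmro2_ratio**beta)``; zero when both
    ratios are one.
    """
    p = get_pairing(pairing)
    if m <= 0.0:
        raise ValueError(f"M must be positive, got {m}")
    if cbf_ratio <= 0.0 or cmro2_ratio <= 0.0:
        raise ValueError(
            f"flow and CMRO2 ratios must be positive, got "
            f"cbf_ratio={cbf_ratio}, cmro2_ratio={cmro2_ratio}"
        )
    return m * (1.0 - cbf_ratio ** (p.alpha - p.beta) * cmro2_ratio**p.beta)


def graded_bold(
    m: float,
    kappa: float,
    cbf_ratio: float,
    delta_petco2: float,
    pairing: "AlphaBetaPairing | str" = "empirical",
) -> float:
    """Davis model with the CMRO2 ratio supplied by the linear dose model."""
    return davis_bold(
        m, cbf_ratio, cmro2_ratio_from_dose(kappa, delta_petco2), pairing
    )


def invert_for_cmro2(
    m: float,
    bold_frac: float,
    cbf_ratio: float,
    pairing: "AlphaBetaPairing | str" = "empirical",
) -> float:
    """Solve the Davis model for the CMRO2 ratio.

    The algebraic inverse ``((1 - b/M) * f**(beta-alpha))**(1/beta)``; the
    round trip with :func:`davis_bold` is the identity.  Raises
    ``ValueError`` when ``bold_frac >= M`` (which would force a non-positive
    CMRO2 ratio).
    """
    p = get_pairing(pairing)
    if m <= 0.0:
        raise ValueError(f"M must be positive, got {m}")
    if cbf_ratio <= 0.0:
        raise ValueError(f"cbf_ratio must be positive, got {cbf_ratio}")
    if bold_frac >= m:
        raise ValueError(
            f"bold_frac={bold_frac} must be below M={m} for a positive "
            "CMRO2 ratio"
        )
    return ((1.0 - bold_frac / m) * cbf_ratio ** (p.beta - p.alpha)) ** (
        1.0 / p.beta
    )


def relative_bold_contrast(te: float, r2star: float) -> float:
    """BOLD contrast of a spoiled gradient echo relative to its optimum.

    Contrast of a TE-weighted acquisition scales as ``TE * exp(-TE * R2*)``,
    maximal at ``TE = 1/R2*``.  Returns the ratio to that maximum, i.e.
    ``TE * R2* * exp(1 - TE * R2*)``, which is 1 at the optimal echo time.

    Parameters
    ----------
    te : float
        Echo time, seconds.
    r2star : float
        Effective transverse relaxation rate, 1/s.
    """
    if te <= 0.0 or r2star <= 0.0:
        raise ValueError(f"te and r2star must be positive, got {te}, {r2star}")
    x = te * r2star
    return x * math.exp(1.0 - x)
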
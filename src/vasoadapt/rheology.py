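"""Empirical haemorheology of microvascular blood flow.

Blood in microvessels behaves as a biphasic fluid: plasma plus discrete
red blood cells (RBCs).  Three empirical in-vitro laws (Pries-Secomb
parameterizations) close the model:

* the relative apparent viscosity ``mu_rel(H, d)`` capturing the
  Fåhraeus-Lindqvist effect,
* the tube-to-discharge haematocrit relation (Fåhraeus effect), and
* the phase-separation law giving the probability that an RBC entering a
  divergent bifurcation is routed into a given daughter vessel.

All functions are pure and operate elementwise on scalars or numpy
arrays.  Units: lengths in µm, viscosity in Pa·ms, volumes in fL (µm³).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RheologyParams",
    "tube_haematocrit",
    "fahraeus_ratio",
    "discharge_from_tube",
    "mu_45",
    "relative_viscosity",
    "phase_separation_probability",
]

#: physical plausibility cap on tube haematocrit (volume packing of RBCs)
HT_WARN_THRESHOLD = 0.9


@dataclass(frozen=True)
class ViscosityLawConstants:
    """Constants of the in-vitro relative apparent viscosity law."""

    a1: float = 220.0
    a2: float = -1.3
    a3: float = 3.2
    a4: float = -2.44
    a5: float = -0.06
    a6: float = 0.645
    reference_haematocrit: float = 0.45


@dataclass(frozen=True)
class PhaseSeparationConstants:
    """Constants of the empirical RBC phase-separation (bifurcation) law."""

    a_coeff: float = -6.96
    b_coeff: float = 6.98
    x0_coeff: float = 0.4


@dataclass(frozen=True)
class RheologyParams:
    """Fluid and RBC parameters of the biphasic blood model.

    Parameters
    ----------
    mu_p
        Plasma dynamic viscosity in Pa·ms (1.2 Pa·ms = 1.2 mPa·s).
    v_rbc
        Volume of a single red blood cell in fL (mouse RBC ≈ 49 fL).
    use_discharge_viscosity
        If True, evaluate the viscosity law with the discharge
        haematocrit instead of the tube haematocrit.  The in-vitro law
        was originally fitted against discharge haematocrit; the model
        implemented here evaluates it with tube haematocrit by default.
    """

    mu_p: float = 1.2
    v_rbc: float = 49.0
    use_discharge_viscosity: bool = False
    viscosity_law: ViscosityLawConstants = field(default_factory=ViscosityLawConstants)
    phase_separation: PhaseSeparationConstants = field(
        default_factory=PhaseSeparationConstants
    )

    def __post_init__(self) -> None:
        if self.mu_p <= 0:
            raise ValueError(f"plasma viscosity must be positive, got {self.mu_p}")
        if self.v_rbc <= 0:
            raise ValueError(f"RBC volume must be positive, got {self.v_rbc}")


def tube_haematocrit(n_rbc, v_rbc: float, d, l) -> np.ndarray | float:
    """Tube haematocrit: RBC volume fraction of a cylindrical vessel.

    ``H_t = n_rbc * V_rbc / (pi/4 * d**2 * l)`` with ``d``, ``l`` in µm
    and ``V_rbc`` in fL.  Warns (without clamping) if the result exceeds
    the physical packing cap of 0.9.
    """
    n_rbc = np.asarray(n_rbc, dtype=float)
    d = np.asarray(d, dtype=float)
    l = np.asarray(l, dtype=float)
    if np.any(n_rbc < 0):
        raise ValueError("RBC count must be non-negative")
    if np.any(d <= 0) or np.any(l <= 0):
        raise ValueError("diameter and length must be positive")
    ht = n_rbc * v_rbc / (0.25 * np.pi * d**2 * l)
    if np.any(ht > HT_WARN_THRESHOLD):
        warnings.warn(
            f"tube haematocrit exceeds {HT_WARN_THRESHOLD} (max {np.max(ht):.3f}); "
            "the vessel is unphysically crowded",
            stacklevel=2,
        )
    if ht.ndim == 0:
        return float(ht)
    return ht


def fahraeus_ratio(d):
    """Asymptotic ratio H_t/H_d at vanishing haematocrit, r(d).

    ``r(d) = 1 + 1.7 exp(-0.415 d) - 0.6 exp(-0.011 d)`` (d in µm);
    r < 1 in microvessels and r → 1 for very wide tubes.
    """
    d = np.asarray(d, dtype=float)
    r = 1.0 + 1.7 * np.exp(-0.415 * d) - 0.6 * np.exp(-0.011 * d)
    if r.ndim == 0:
        return float(r)
    return r


def discharge_from_tube(h_t, d) -> np.ndarray | float:
    """Discharge haematocrit H_d from tube haematocrit H_t (Fåhraeus effect).

    Inverts the empirical relation ``H_t/H_d = H_d + (1 - H_d) r(d)``,
    a quadratic in H_d solved in closed form:

    ``(1 - r) H_d**2 + r H_d - H_t = 0``

    The physical root satisfies ``H_t <= H_d <= 1`` wherever r(d) < 1
    (all of the capillary range, d ≳ 2.5 µm): RBCs travel faster than
    the bulk, so a vessel's content is depleted relative to its outflow.
    Below the size of a red blood cell the empirical fit loses this
    property; the quadratic root is still returned.
    """
    h_t = np.asarray(h_t, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any((h_t < 0) | (h_t > 1)):
        raise ValueError("tube haematocrit must lie in [0, 1]")
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    r = np.asarray(fahraeus_ratio(d), dtype=float)
    h_t, r = np.broadcast_arrays(h_t, r)
    a = 1.0 - r
    disc = r**2 + 4.0 * a * h_t
    if np.any(disc < 0):  # cannot occur for valid inputs; guard anyway
        raise ValueError("no real root for the Fåhraeus relation")
    with np.errstate(divide="ignore", invalid="ignore"):
        h_d = np.where(
            np.abs(a) > 1e-12,
            (-r + np.sqrt(disc)) / (2.0 * np.where(np.abs(a) > 1e-12, a, 1.0)),
            h_t / np.where(np.abs(r) > 0, r, 1.0),
        )
    h_d = np.clip(h_d, 0.0, 1.0)
    if h_d.ndim == 0:
        return float(h_d)
    return h_d


def mu_45(d, constants: ViscosityLawConstants | None = None):
    """Relative apparent viscosity at the reference haematocrit 0.45.

    ``mu_0.45(d) = 220 exp(-1.3 d) + 3.2 - 2.44 exp(-0.06 d**0.645)``.
    """
    c = constants or ViscosityLawConstants()
    d = np.asarray(d, dtype=float)
    out = c.a1 * np.exp(c.a2 * d) + c.a3 + c.a4 * np.exp(c.a5 * d**c.a6)
    if out.ndim == 0:
        return float(out)
    return out


def _shape_exponent(d):
    """Diameter-dependent exponent C of the viscosity law."""
    d = np.asarray(d, dtype=float)
    steep = 1.0 / (1.0 + 1e-11 * d**12)
    return (0.8 + np.exp(-0.075 * d)) * (-1.0 + steep) + steep


def relative_viscosity(
    h, d, constants: ViscosityLawConstants | None = None
) -> np.ndarray | float:
    """Relative apparent viscosity of blood in a tube of diameter ``d`` µm.

    In-vitro empirical law (Fåhraeus-Lindqvist effect):

    ``mu_rel = 1 + (mu_0.45 - 1) * ((1-H)**C - 1) / ((1-0.45)**C - 1)``

    with the diameter-dependent exponent ``C(d)``.  ``mu_rel >= 1`` for
    any haematocrit ``H in [0, 1)`` and ``mu_rel(0, d) = 1`` exactly.
    """
    c = constants or ViscosityLawConstants()
    h = np.asarray(h, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(h >= 1.0) or np.any(h < 0.0):
        raise ValueError("haematocrit must lie in [0, 1)")
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    exponent = _shape_exponent(d)
    m45 = np.asarray(mu_45(d, c), dtype=float)
    href = c.reference_haematocrit
    ratio = ((1.0 - h) ** exponent - 1.0) / ((1.0 - href) ** exponent - 1.0)
    out = 1.0 + (m45 - 1.0) * ratio
    if out.ndim == 0:
        return float(out)
    return out


def _logit(x):
    return np.log(x / (1.0 - x))


def phase_separation_probability(
    fq_b: float,
    h_d_parent: float,
    d_parent: float,
    d_a: float,
    d_b: float,
    constants: PhaseSeparationConstants | None = None,
) -> float:
    """Probability that an RBC leaving a divergent bifurcation enters daughter a.

    Empirical logit law: with ``X0 = 0.4 / D_parent``,

    * ``FQ_B <= X0``      → 0 (daughter a receives too little flow for RBCs),
    * ``FQ_B >= 1 - X0``  → 1,
    * otherwise ``logit(FQ_E) = A + B logit((FQ_B - X0) / (1 - 2 X0))``

    where ``FQ_B`` is the fraction of blood flow entering daughter a,
    ``A = -6.96 / D_parent * ln(D_a / D_b)`` penalizes the wider daughter
    asymmetry, and ``B = 1 + 6.98 (1 - H_d_parent) / D_parent`` sharpens
    partitioning at low haematocrit.  Diameters in µm.
    """
    c = constants or PhaseSeparationConstants()
    if not 0.0 <= fq_b <= 1.0:
        raise ValueError("fractional blood flow must lie in [0, 1]")
    if d_parent <= 0 or d_a <= 0 or d_b <= 0:
        raise ValueError("diameters must be positive")
    if not 0.0 <= h_d_parent < 1.0:
        raise ValueError("parent discharge haematocrit must lie in [0, 1)")
    x0 = c.x0_coeff / d_parent
    if fq_b <= x0:
        return 0.0
    if fq_b >= 1.0 - x0:
        return 1.0
    a = c.a_coeff / d_parent * np.log(d_a / d_b)
    b = 1.0 + c.b_coeff * (1.0 - h_d_parent) / d_parent
    z = a + b * _logit((fq_b - x0) / (1.0 - 2.0 * x0))
    return float(1.0 / (1.0 + np.exp(-z)))
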
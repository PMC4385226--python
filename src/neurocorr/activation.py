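"""Sigmoidal activation functions mapping membrane potential to firing rate.

Each family maps a potential ``V`` to a rate in ``(0, nu_max)``; ``Lambda``
controls the slope of the transition and ``V_T`` is the threshold potential
at which the rate equals ``nu_max / 2``.  The derivative (local gain) is
strictly positive, which is what makes the linearization around an
equilibrium well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

__all__ = ["ActivationSpec", "FAMILIES"]

FAMILIES = ("logistic", "inverse_tangent", "gauss_error", "algebraic", "gompertz")

#: families for which the distance to the nearest complex singularity of the
#: analytic continuation is known in closed form
_RADIUS_FAMILIES = ("logistic", "inverse_tangent")


@dataclass(frozen=True)
class ActivationSpec:
    """A sigmoid ``A(V)`` with maximum rate ``nu_max``, slope ``Lambda`` and
    threshold ``V_T``.

    The object is callable: ``spec(V)`` returns the rate, ``spec.derivative(V)``
    the gain ``A'(V)``.  All five families satisfy ``A(V_T) = nu_max / 2``
    (for Gompertz because ``2**(-exp(0)) = 1/2``) and share the threshold
    slope ``A'(V_T) = nu_max * Lambda / 4``.
    """

    family: str = "logistic"
    nu_max: float = 1.0
    Lambda: float = 1.0
    V_T: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown activation family {self.family!r}; "
                f"supported families: {', '.join(FAMILIES)}"
            )
        if not self.nu_max > 0:
            raise ValueError("nu_max must be positive")
        if not self.Lambda > 0:
            raise ValueError("Lambda must be positive")

    # -- evaluation ---------------------------------------------------------

    def __call__(self, V):
        u = np.asarray(V, dtype=float) - self.V_T
        nm, L = self.nu_max, self.Lambda
        if self.family == "logistic":
            out = nm / (1.0 + np.exp(-L * u))
        elif self.family == "inverse_tangent":
            out = nm * (0.5 + np.arctan(np.pi * L * u / 4.0) / np.pi)
        elif self.family == "gauss_error":
            out = 0.5 * nm * (1.0 + erf(np.sqrt(np.pi) * L * u / 4.0))
        elif self.family == "algebraic":
            x = 0.5 * L * u
            out = 0.5 * nm * (1.0 + x / np.sqrt(1.0 + x * x))
        else:  # gompertz
            a = L / (2.0 * np.log(2.0))
            out = nm * np.exp2(-np.exp(-a * u))
        return out if np.ndim(V) else float(out)

    def derivative(self, V):
        """Gain ``A'(V)``; strictly positive for every finite ``V``."""
        u = np.asarray(V, dtype=float) - self.V_T
        nm, L = self.nu_max, self.Lambda
        if self.family == "logistic":
            X = nm / (1.0 + np.exp(-L * u))
            # the logistic gain obeys X' = Lambda * (X - X^2 / nu_max)
            out = L * (X - X * X / nm)
        elif self.family == "inverse_tangent":
            x = np.pi * L * u / 4.0
            out = (nm * L / 4.0) / (1.0 + x * x)
        elif self.family == "gauss_error":
            out = (nm * L / 4.0) * np.exp(-np.pi * (L * u) ** 2 / 16.0)
        elif self.family == "algebraic":
            out = (nm * L / 4.0) * (1.0 + (L * u) ** 2 / 4.0) ** -1.5
        else:  # gompertz
            a = L / (2.0 * np.log(2.0))
            e = np.exp(-a * u)
            out = nm * np.log(2.0) * a * e * np.exp2(-e)
        return out if np.ndim(V) else float(out)

    # -- analyticity --------------------------------------------------------

    def radius_of_convergence(self, mu):
        """Radius of convergence of the Taylor series of ``A`` about ``mu``.

        Equals the distance from ``mu`` to the nearest singularity of the
        analytic continuation: the logistic has poles at
        ``V_T + i*pi*(2k+1)/Lambda`` and the inverse tangent has branch
        points at ``V_T +/- 4i/(pi*Lambda)``, so in both cases the radius is
        ``sqrt((mu - V_T)**2 + d**2)`` with ``d`` the imaginary offset.  It
        shrinks as ``Lambda`` grows and grows with ``|mu - V_T|``.
        """
        if self.family not in _RADIUS_FAMILIES:
            raise NotImplementedError(
                f"radius of convergence implemented only for "
                f"{', '.join(_RADIUS_FAMILIES)}, not {self.family!r}"
            )
        u = np.asarray(mu, dtype=float) - self.V_T
        if self.family == "logistic":
            d = np.pi / self.Lambda
        else:
            d = 4.0 / (np.pi * self.Lambda)
        out = np.sqrt(u * u + d * d)
        return out if np.ndim(mu) else float(out)
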
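"""Neo-Hookean elasticity with multiplicative tangential growth.

The tissue is a modestly compressible neo-Hookean solid with strain energy
density

    W(F) = mu/2 [ Tr(F F^T) J^{-2/3} - 3 ] + K/2 (J - 1)^2,     J = det F,

split into an isochoric part (shear modulus ``mu``) and a volumetric part
(bulk modulus ``K``, default 5 mu).  Cortical growth enters through the
multiplicative decomposition F = Fe G: the growth tensor G stretches the two
directions tangential to the local surface normal n by the effective ratio
g_eff and leaves the normal direction unchanged,

    G = g_eff (I - n n^T) + n n^T,        det G = g_eff^2,

so the areal expansion of the cortex relative to the white matter is g^2.
Stress and energy are always evaluated on the elastic part Fe = F G^{-1}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MaterialParams",
    "DeformationGradient",
    "GrowthTensorSpec",
    "InvertedElementError",
    "neo_hookean_energy",
    "first_piola_stress",
    "growth_tensor",
    "effective_stretch",
    "elastic_part",
]


class InvertedElementError(ValueError):
    """J <= 0: the deformation is inverted; route through inversion handling."""


@dataclass(frozen=True)
class MaterialParams:
    """Shear modulus mu (stress scale, nondimensional default 1) and bulk
    modulus K (default 5 mu, a modestly compressible tissue)."""

    mu: float = 1.0
    K_bulk: float = 5.0

    def __post_init__(self):
        if not (self.mu > 0 and self.K_bulk > 0):
            raise ValueError("mu and K_bulk must be positive")


@dataclass(frozen=True)
class DeformationGradient:
    """A 3x3 deformation gradient with its cached determinant."""

    F: np.ndarray
    J: float = None  # type: ignore[assignment]

    def __post_init__(self):
        F = np.asarray(self.F, dtype=float)
        if F.shape != (3, 3):
            raise ValueError("F must be a 3x3 matrix")
        object.__setattr__(self, "F", F)
        J = float(np.linalg.det(F))
        if self.J is not None and abs(self.J - J) > 1e-12 * max(1.0, abs(J)):
            raise ValueError("stored J is inconsistent with det(F)")
        object.__setattr__(self, "J", J)

    @property
    def inverted(self) -> bool:
        return self.J <= 0.0


def _as_F(Fe) -> tuple[np.ndarray, float]:
    if isinstance(Fe, DeformationGradient):
        return Fe.F, Fe.J
    F = np.asarray(Fe, dtype=float)
    return F, float(np.linalg.det(F))


def neo_hookean_energy(Fe, mat: MaterialParams = MaterialParams()) -> float:
    """Energy density W(Fe); Fe must be non-inverted (J > 0).

    W >= 0 always, with equality exactly when Fe is a rotation.
    """
    F, J = _as_F(Fe)
    if J <= 0.0:
        raise InvertedElementError(
            f"J = {J:.3e} <= 0; use the solver's inversion handling for "
            "inverted states"
        )
    I1 = float(np.einsum("ij,ij->", F, F))
    return 0.5 * mat.mu * (I1 * J ** (-2.0 / 3.0) - 3.0) + 0.5 * mat.K_bulk * (J - 1.0) ** 2


def first_piola_stress(Fe, mat: MaterialParams = MaterialParams()) -> np.ndarray:
    """First Piola-Kirchhoff stress P = dW/dF of the energy above:

    P = mu J^{-2/3} (F - Tr(F F^T)/3 F^{-T}) + K J (J - 1) F^{-T}.
    """
    F, J = _as_F(Fe)
    if J <= 0.0:
        raise InvertedElementError(f"J = {J:.3e} <= 0; stress undefined")
    Finv = np.linalg.inv(F)
    FinvT = Finv.T
    I1 = float(np.einsum("ij,ij->", F, F))
    P = mat.mu * J ** (-2.0 / 3.0) * (F - (I1 / 3.0) * FinvT)
    P += mat.K_bulk * J * (J - 1.0) * FinvT
    return P


@dataclass(frozen=True)
class GrowthTensorSpec:
    """Tangential growth of one element.

    ``n_hat`` is the reference surface-normal direction, ``g_schedule`` the
    currently scheduled tangential stretch of fully cortical tissue (ramped
    from 1 toward the target g, default 1.9), and ``theta`` the gray-matter
    indicator grading the growth into the white matter.  ``masked`` elements
    never grow.  The effective stretch is g_eff = 1 + theta (g_schedule - 1).
    """

    n_hat: tuple
    g_schedule: float = 1.9
    theta: float = 1.0
    masked: bool = False

    def __post_init__(self):
        n = np.asarray(self.n_hat, dtype=float)
        if n.shape != (3,):
            raise ValueError("n_hat must be a 3-vector")
        if abs(np.linalg.norm(n) - 1.0) > 1e-8:
            raise ValueError("n_hat must be a unit vector (|n| = 1 within 1e-8)")
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")
        object.__setattr__(self, "n_hat", tuple(float(x) for x in n))

    @property
    def g_effective(self) -> float:
        if self.masked:
            return 1.0
        return effective_stretch(self.g_schedule, self.theta)


def effective_stretch(g_schedule: float, theta) -> float | np.ndarray:
    """Linear-in-stretch blend through the gray/white transition:
    g_eff = 1 + theta (g_schedule - 1)."""
    return 1.0 + np.asarray(theta) * (g_schedule - 1.0)


def growth_tensor(spec: GrowthTensorSpec) -> np.ndarray:
    """G = g_eff (I - n n^T) + n n^T; det G = g_eff^2 (areal growth g^2)."""
    n = np.asarray(spec.n_hat)
    g = spec.g_effective
    return g * (np.eye(3) - np.outer(n, n)) + np.outer(n, n)


def elastic_part(F_total: np.ndarray, G: np.ndarray) -> DeformationGradient:
    """Multiplicative split: Fe = F_total G^{-1} (stress-free when F = G)."""
    G = np.asarray(G, dtype=float)
    detG = float(np.linalg.det(G))
    if detG <= 0 or not np.isfinite(detG):
        raise ValueError(f"growth tensor must have positive determinant, got {detG:.3e}")
    Fe = np.asarray(F_total, dtype=float) @ np.linalg.inv(G)
    return DeformationGradient(Fe)
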
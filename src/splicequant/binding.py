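"""Quadratic total-anisotropy binding isotherm and its least-squares fit.

For a 1:1 protein–RNA equilibrium followed by fluorescence anisotropy at
fixed labelled-RNA concentration, the measured (total) anisotropy is the
bound-fraction mixture of the free-RNA and complex anisotropies. Solving
the mass balance exactly (no free-ligand approximation, appropriate when
RNA and Kd are of comparable magnitude) gives

    A_T = A_R + (A_PR - A_R)/R_T * ( (P_T + R_T + Kd)/2
          - sqrt( ((P_T + R_T + Kd)/2)^2 - P_T * R_T ) )

with A_R the anisotropy of unbound RNA, A_PR that of the complex, P_T and
R_T the total protein and RNA concentrations (molar) and Kd the
dissociation constant. The bracket is the equilibrium complex
concentration, the smaller root of the mass-balance quadratic.

Fitting is unweighted nonlinear least squares on (Kd, A_R, A_PR) with R_T
a fixed known constant of the assay (typically 20 nM labelled oligo).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["anisotropy_model", "fit_binding", "BindingFit", "BindingFitError"]

logger = logging.getLogger(__name__)

_KD_LOWER = 1e-15  # molar; effectively stoichiometric binding


class BindingFitError(RuntimeError):
    """Raised when the titration cannot identify the binding parameters."""


def anisotropy_model(protein_total, rna_total: float, kd: float, a_free: float, a_bound: float):
    """Total anisotropy A_T at the given total protein concentration(s).

    Vectorised over ``protein_total``. A discriminant driven slightly
    negative by rounding is clamped to zero (exact stoichiometric
    saturation).
    """
    if rna_total <= 0:
        raise ValueError("rna_total must be positive")
    if kd < 0:
        raise ValueError("kd must be non-negative")
    p = np.asarray(protein_total, dtype=float)
    if np.any(p < 0):
        raise ValueError("protein_total must be non-negative")
    half_sum = (p + rna_total + kd) / 2.0
    disc = half_sum**2 - p * rna_total
    complex_conc = half_sum - np.sqrt(np.maximum(disc, 0.0))
    out = a_free + (a_bound - a_free) / rna_total * complex_conc
    return float(out) if np.isscalar(protein_total) else out


@dataclass
class BindingFit:
    """Fitted Eq.-style isotherm parameters with standard errors."""

    kd: float
    a_free: float
    a_bound: float
    rna_total: float
    residual_sse: float
    kd_se: float
    a_free_se: float
    a_bound_se: float
    n: int
    warnings: list[str] = field(default_factory=list)

    def predict(self, protein_total):
        return anisotropy_model(protein_total, self.rna_total, self.kd, self.a_free, self.a_bound)


def _initial_guess(p: np.ndarray, a: np.ndarray) -> tuple[float, float, float]:
    order = np.argsort(p)
    p_sorted, a_sorted = p[order], a[order]
    a_free0 = float(a_sorted[0])  # anisotropy at lowest protein
    a_bound0 = float(a_sorted[-1])  # anisotropy at highest protein
    half_signal = (a_free0 + a_bound0) / 2.0
    # protein concentration at half signal; fall back to the median titration point
    if a_bound0 != a_free0:
        direction = 1.0 if a_bound0 > a_free0 else -1.0
        kd0 = float(np.interp(direction * half_signal, direction * a_sorted, p_sorted))
    else:
        kd0 = float(np.median(p_sorted))
    kd0 = max(kd0, _KD_LOWER)
    return kd0, a_free0, a_bound0


def fit_binding(
    protein_total: Sequence[float],
    anisotropy: Sequence[float],
    rna_total: float,
) -> BindingFit:
    """Fit (Kd, A_R, A_PR) to a titration by nonlinear least squares.

    Deterministic given the data: initial values are A_R = anisotropy at
    the lowest protein point, A_PR = at the highest, Kd = protein
    concentration at half-signal. Fewer than 5 distinct protein
    concentrations, an estimate outside the titrated range, Kd at its
    lower bound, or A_PR < A_R are flagged in ``fit.warnings``; constant
    anisotropy raises :class:`BindingFitError` (unidentifiable), as does
    non-convergence.
    """
    p = np.asarray(protein_total, dtype=float)
    a = np.asarray(anisotropy, dtype=float)
    if p.shape != a.shape or p.ndim != 1:
        raise ValueError("protein_total and anisotropy must be matching 1-D sequences")
    if p.size < 3:
        raise BindingFitError("need at least 3 titration points")
    if np.ptp(a) == 0:
        raise BindingFitError("constant anisotropy: binding parameters are unidentifiable")
    warnings: list[str] = []
    if np.unique(p).size < 5:
        warnings.append("fewer than 5 distinct protein concentrations; Kd poorly constrained")

    kd0, a_free0, a_bound0 = _initial_guess(p, a)

    def model(pp, kd, a_free, a_bound):
        return anisotropy_model(pp, rna_total, kd, a_free, a_bound)

    try:
        popt, pcov = curve_fit(
            model,
            p,
            a,
            p0=[kd0, a_free0, a_bound0],
            bounds=([_KD_LOWER, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise BindingFitError(f"nonlinear least squares did not converge: {exc}") from exc
    kd, a_free, a_bound = (float(v) for v in popt)
    se = np.sqrt(np.diag(pcov))
    if not np.all(np.isfinite(se)):
        warnings.append("parameter covariance not estimable; standard errors unreliable")
    if kd <= 2 * _KD_LOWER:
        warnings.append("Kd hit its lower bound (stoichiometric regime); value not meaningful")
    if p.max() > 0 and kd > float(p.max()):
        warnings.append("fitted Kd exceeds the highest titrated concentration")
    if a_bound < a_free:
        warnings.append("fitted A_PR < A_R: anisotropy decreases on binding")
    resid = a - model(p, kd, a_free, a_bound)
    for msg in warnings:
        logger.warning("fit_binding: %s", msg)
    return BindingFit(
        kd=kd,
        a_free=a_free,
        a_bound=a_bound,
        rna_total=rna_total,
        residual_sse=float(resid @ resid),
        kd_se=float(se[0]),
        a_free_se=float(se[1]),
        a_bound_se=float(se[2]),
        n=int(p.size),
        warnings=warnings,
    )
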
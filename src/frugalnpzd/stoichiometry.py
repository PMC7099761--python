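"""Nutrient limitation and variable N:P stoichiometry.

This module holds the chemical core of the model: squared Michaelis-Menten
limitation factors for dissolved inorganic nitrogen and phosphate, the
Liebig minimum rule that selects the limiting nutrient, and the internal
P:N uptake ratio of phytoplankton under two policies:

``redfield``
    The classical fixed ratio P:N = 1/16 — organic matter is produced at
    16 mol N per mol P regardless of ambient chemistry.

``lof``
    The "line of frugality": an empirical linear dependence of the P:C
    content of organic matter on ambient phosphate.  Combined with a
    constant N:C of 144 per mille this yields a phosphate-dependent P:N
    uptake ratio::

        p_to_n(PO4) = (6.9 * PO4 + 6) / 144

    with PO4 in mmol P m^-3.  At PO4 = 0 the organic-matter N:P reaches
    its ceiling of 24; the rule crosses Redfield (1/16) at
    PO4 = 3/6.9 ~ 0.435 mmol P m^-3.

All functions accept scalars or NumPy arrays and are pure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np

ArrayLike = Union[float, np.ndarray]

#: Canonical fixed P:N molar ratio of marine organic matter.
REDFIELD_P_TO_N = 1.0 / 16.0

#: Slope of the line of frugality: per-mille P:C per (mmol P m^-3).
LOF_SLOPE = 6.9

#: Intercept of the line of frugality (per mille P:C at PO4 = 0).
LOF_INTERCEPT = 6.0

#: Constant N:C ratio of organic matter (per mille).
N_TO_C = 144.0


class UndefinedRatio(float):
    """Marker type: N:P of water where phosphate is exactly zero."""


@dataclass(frozen=True)
class StoichiometryPolicy:
    """Uptake-ratio rule (fixed Redfield or variable line of frugality).

    Parameters
    ----------
    mode
        ``"redfield"`` or ``"lof"``.
    redfield_p_to_n
        P:N molar ratio used in redfield mode; must equal 1/16 there.
    lof_slope, lof_intercept
        Constants of the P:C vs PO4 line (per mille, per mille per
        mmol P m^-3).
    n_to_c
        Constant N:C ratio of organic matter (per mille).
    """

    mode: str
    redfield_p_to_n: float = REDFIELD_P_TO_N
    lof_slope: float = LOF_SLOPE
    lof_intercept: float = LOF_INTERCEPT
    n_to_c: float = N_TO_C

    def __post_init__(self) -> None:
        if self.mode not in ("redfield", "lof"):
            raise ValueError(
                f"unknown stoichiometry mode {self.mode!r}; "
                "expected 'redfield' or 'lof'"
            )
        if self.mode == "redfield" and self.redfield_p_to_n != REDFIELD_P_TO_N:
            raise ValueError(
                "redfield mode requires the canonical P:N of exactly 1/16, "
                f"got {self.redfield_p_to_n!r}"
            )
        if self.lof_slope <= 0 or self.lof_intercept <= 0:
            raise ValueError("line-of-frugality constants must be positive")
        if self.n_to_c <= self.lof_intercept:
            raise ValueError(
                "n_to_c must exceed lof_intercept so the organic N:P "
                "stays bounded above 1 over the valid phosphate range"
            )

    @classmethod
    def redfield(cls) -> "StoichiometryPolicy":
        return cls(mode="redfield")

    @classmethod
    def lof(cls) -> "StoichiometryPolicy":
        return cls(mode="lof")


@dataclass(frozen=True)
class NutrientConcentrations:
    """Dissolved inorganic nutrient concentrations (mmol m^-3)."""

    no3: ArrayLike
    nh4: ArrayLike
    po4: ArrayLike

    def __post_init__(self) -> None:
        for name in ("no3", "nh4", "po4"):
            val = np.asarray(getattr(self, name), dtype=float)
            if np.any(val < 0):
                raise ValueError(
                    f"negative {name} concentration: {float(np.min(val))}"
                )

    @property
    def din(self) -> ArrayLike:
        """Dissolved inorganic nitrogen, NH4 + NO3."""
        return np.asarray(self.nh4, float) + np.asarray(self.no3, float)


@dataclass(frozen=True)
class LimitationResult:
    """Outcome of the Liebig minimum rule for one nutrient environment."""

    nlim: ArrayLike
    plim: ArrayLike
    limiting: Union[str, np.ndarray]
    factor: ArrayLike


def _scalarize(x: np.ndarray, scalar: bool) -> ArrayLike:
    return float(x) if scalar else x


def _check_po4(po4: ArrayLike) -> np.ndarray:
    arr = np.asarray(po4, dtype=float)
    if np.any(arr < 0):
        raise ValueError(
            f"negative phosphate concentration: {float(np.min(arr))} mmol P m^-3"
        )
    return arr


def p_to_n_ratio(policy: StoichiometryPolicy, po4: ArrayLike) -> ArrayLike:
    """Internal P:N molar uptake ratio of organic matter.

    Redfield mode returns the constant 1/16; lof mode returns the
    phosphate-dependent ratio ``(slope * po4 + intercept) / n_to_c``,
    strictly increasing in phosphate.
    """
    arr = _check_po4(po4)
    scalar = np.ndim(po4) == 0
    if policy.mode == "redfield":
        out = np.full_like(arr, policy.redfield_p_to_n)
    else:
        out = (policy.lof_slope * arr + policy.lof_intercept) / policy.n_to_c
    return _scalarize(out, scalar)


def np_om(policy: StoichiometryPolicy, po4: ArrayLike) -> ArrayLike:
    """Organic-matter N:P molar ratio, the reciprocal of the uptake ratio.

    In lof mode this is strictly decreasing in phosphate with a supremum
    of ``n_to_c / lof_intercept`` (= 24 with the default constants) at
    zero phosphate.
    """
    ratio = p_to_n_ratio(policy, po4)
    return 1.0 / ratio if np.ndim(ratio) == 0 else 1.0 / np.asarray(ratio)


def redfield_crossing_po4(policy: StoichiometryPolicy) -> float:
    """Phosphate concentration where the lof ratio equals Redfield 1/16."""
    return (policy.n_to_c * REDFIELD_P_TO_N - policy.lof_intercept) / policy.lof_slope


def nitrogen_limitation(din: ArrayLike, alpha: float) -> ArrayLike:
    """Squared Michaelis-Menten nitrogen limitation, D^2 / (alpha^2 + D^2).

    ``din`` is NH4 + NO3 (mmol N m^-3); ``alpha`` is the half-saturation
    constant in the same units.  Result lies in [0, 1) and equals 0.5
    exactly at ``din == alpha``.
    """
    if alpha <= 0:
        raise ValueError(f"half-saturation alpha must be positive, got {alpha}")
    d = np.asarray(din, dtype=float)
    out = d * d / (alpha * alpha + d * d)
    return _scalarize(out, np.ndim(din) == 0)


def phosphorus_limitation(
    po4: ArrayLike, alpha: float, p_to_n: ArrayLike
) -> ArrayLike:
    """Squared Michaelis-Menten phosphate limitation.

    The nitrogen-unit half-saturation ``alpha`` is rescaled into
    phosphorus units by the internal P:N ratio, giving
    ``po4^2 / ((p_to_n * alpha)^2 + po4^2)``.  Under the variable-ratio
    policy the half-saturation — and hence the N-vs-P limitation
    threshold — shifts with ambient phosphate.
    """
    if alpha <= 0:
        raise ValueError(f"half-saturation alpha must be positive, got {alpha}")
    p = _check_po4(po4)
    ratio = np.asarray(p_to_n, dtype=float)
    if np.any(ratio <= 0):
        raise ValueError("p_to_n ratio must be strictly positive")
    half = ratio * alpha
    out = p * p / (half * half + p * p)
    return _scalarize(out, np.ndim(po4) == 0 and np.ndim(p_to_n) == 0)


def nlim(nuts: NutrientConcentrations, alpha: float) -> ArrayLike:
    """Nitrogen limitation factor for a nutrient environment."""
    return nitrogen_limitation(nuts.din, alpha)


def plim(
    nuts: NutrientConcentrations, alpha: float, p_to_n: ArrayLike
) -> ArrayLike:
    """Phosphate limitation factor for a nutrient environment."""
    return phosphorus_limitation(nuts.po4, alpha, p_to_n)


def limitation(
    nuts: NutrientConcentrations, alpha: float, policy: StoichiometryPolicy
) -> LimitationResult:
    """Apply the Liebig minimum rule: the lower of nlim and plim limits.

    The phosphate half-saturation is evaluated with the uptake ratio at
    the *same* ambient phosphate, so in lof mode the decision boundary
    between nitrogen and phosphorus limitation moves with PO4.
    """
    ratio = p_to_n_ratio(policy, nuts.po4)
    n = nlim(nuts, alpha)
    p = plim(nuts, alpha, ratio)
    scalar = np.ndim(n) == 0 and np.ndim(p) == 0
    n_arr, p_arr = np.asarray(n, float), np.asarray(p, float)
    limiting = np.where(
        n_arr < p_arr, "nitrogen", np.where(p_arr < n_arr, "phosphorus", "tie")
    )
    factor = np.minimum(n_arr, p_arr)
    if scalar:
        return LimitationResult(
            nlim=float(n_arr), plim=float(p_arr),
            limiting=str(limiting), factor=float(factor),
        )
    return LimitationResult(nlim=n_arr, plim=p_arr, limiting=limiting, factor=factor)


def np_water(no3: ArrayLike, po4: ArrayLike) -> ArrayLike:
    """Inorganic N:P of seawater, nitrate over phosphate.

    Where phosphate is exactly zero the ratio is undefined; those entries
    are returned as NaN (a flagged sentinel) rather than infinity, so
    gridded diagnostics never abort mid-run.  Scalar zero-phosphate input
    returns an :class:`UndefinedRatio` NaN.
    """
    n = np.asarray(no3, dtype=float)
    p = np.asarray(po4, dtype=float)
    scalar = np.ndim(no3) == 0 and np.ndim(po4) == 0
    out = np.full(np.broadcast(n, p).shape, np.nan)
    np.divide(n, p, out=out, where=p > 0)
    if scalar:
        val = float(out)
        return UndefinedRatio(math.nan) if p == 0 else val
    return out
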
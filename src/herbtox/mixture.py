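"""Concentration-addition mixture toxicity and atrazine toxic equivalents.

Under concentration addition (CA), a mixture with component concentrations
``c_i`` produces effect level ``x*`` where the toxic units sum to one:

    sum_i c_i / ECx_i(x*) = 1

The equi-effective atrazine concentration (TEQ) of a residue mixture is the
reference-substance concentration producing the same effect,
``TEQ = ECx_ref(x*)``.  A fixed-ratio toxic-equivalency-factor (TEF) shortcut
``sum_i c_i * EC50_ref / EC50_i`` is also provided; it agrees with the full CA
solve exactly when every curve is a parallel shift of the reference and is
labelled approximate otherwise.

Concentrations below the limit of quantification enter as zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

from scipy.optimize import brentq

from .dose_response import FitResult, ResponseModel, ecx

__all__ = [
    "HerbicideCurveDB",
    "SaturatedMixtureWarning",
    "toxic_units",
    "mixture_effect_ca",
    "teq_atrazine",
    "teq_tef_approx",
]

#: bracket offset and solver tolerance for the CA root solve (deterministic)
_X_EPS = 1e-8
_X_TOL = 1e-10

REFERENCE_HERBICIDE = "atrazine"


class SaturatedMixtureWarning(UserWarning):
    """The mixture effect lies at or above the smallest attainable maximum."""


@dataclass(frozen=True)
class HerbicideCurveDB:
    """Per-herbicide response curves plus the reference substance (atrazine)."""

    curves: Mapping[str, ResponseModel]
    reference: str = REFERENCE_HERBICIDE

    def __post_init__(self) -> None:
        if self.reference not in self.curves:
            raise ValueError(f"reference substance {self.reference!r} missing from curves")

    @classmethod
    def from_fit_results(cls, fits: Mapping[str, FitResult],
                         reference: str = REFERENCE_HERBICIDE) -> "HerbicideCurveDB":
        return cls({name: f.model for name, f in fits.items()}, reference)

    def __getitem__(self, name: str) -> ResponseModel:
        return self.curves[name]

    def __contains__(self, name: str) -> bool:
        return name in self.curves

    def min_theta_max(self, names=None) -> float:
        names = self.curves.keys() if names is None else names
        return min(self.curves[n].theta_max for n in names)


def _positive_components(sample: Mapping[str, float], db: HerbicideCurveDB):
    missing = sorted(n for n, c in sample.items() if c > 0 and n not in db)
    if missing:
        raise KeyError(f"herbicides absent from curve database: {missing}")
    for name, c in sample.items():
        if c < 0:
            raise ValueError(f"negative concentration for {name!r}: {c}")
    return {n: c for n, c in sample.items() if c > 0}


def toxic_units(sample: Mapping[str, float], db: HerbicideCurveDB,
                x: float = 0.5) -> dict[str, float]:
    """Toxic unit of every component at effect level ``x``: TU_i = c_i / ECx_i."""
    pos = _positive_components(sample, db)
    tu = {name: 0.0 for name in sample}
    for name, c in pos.items():
        tu[name] = c / ecx(db[name], x)
    return tu


def mixture_effect_ca(sample: Mapping[str, float], db: HerbicideCurveDB) -> float:
    """Mixture effect level ``x*`` under concentration addition.

    Solves ``sum_i c_i / ECx_i(x) = 1`` for x by bracketed root finding on
    ``(1e-8, min theta_max - 1e-8)``.  Returns 0 for an all-zero sample.  When
    the toxic-unit sum still exceeds 1 at the upper bracket the mixture is
    saturated: a :class:`SaturatedMixtureWarning` is issued and the upper
    bracket is returned rather than extrapolating beyond any curve's maximum.
    """
    pos = _positive_components(sample, db)
    if not pos:
        return 0.0

    def tu_sum_minus_one(x: float) -> float:
        return sum(c / ecx(db[n], x) for n, c in pos.items()) - 1.0

    hi = db.min_theta_max(pos) - _X_EPS
    lo = _X_EPS
    if tu_sum_minus_one(hi) > 0.0:
        warnings.warn(
            "mixture effect at or above the smallest theta_max; returning the bracket top",
            SaturatedMixtureWarning,
            stacklevel=2,
        )
        return hi
    if tu_sum_minus_one(lo) < 0.0:  # effectively zero mixture
        return 0.0
    return float(brentq(tu_sum_minus_one, lo, hi, xtol=_X_TOL * 1e-2, rtol=8.9e-16))


def teq_atrazine(sample: Mapping[str, float], db: HerbicideCurveDB) -> float:
    """Equi-effective concentration of the reference substance (nmol/L).

    ``TEQ = ECx_ref(x*)`` with ``x*`` the CA mixture effect; a sample holding
    only the reference at concentration c returns c.
    """
    x_star = mixture_effect_ca(sample, db)
    if x_star <= 0.0:
        return 0.0
    ref = db[db.reference]
    if x_star >= ref.theta_max:
        x_star = ref.theta_max - _X_EPS
    return ecx(ref, x_star)


def teq_tef_approx(sample: Mapping[str, float], db: HerbicideCurveDB) -> float:
    """Fixed-ratio TEF approximation ``sum_i c_i * EC50_ref / EC50_i``.

    Exact only when every component curve is a parallel shift of the
    reference; use :func:`teq_atrazine` for the effect-level-consistent value.
    """
    pos = _positive_components(sample, db)
    ref_ec50 = db[db.reference].ec50
    return sum(c * ref_ec50 / db[n].ec50 for n, c in pos.items())
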
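"""Closed-form biophysics of phage coinfection and the lysogeny decision.

In a well-mixed volume the rate at which phages adsorb to one bacterium is
``P_i * alpha`` (phage concentration times the adsorption rate constant, a
Smoluchowski encounter rate).  Multiplying by the lysogenic commitment time
``tau`` — the window during which later-arriving phages can still sway the
lysis/lysogeny decision of the first — gives the mean number of (co)infections
per cell:

    COI = P_i * alpha * tau

Treating infections as independent arrivals, the number of infections within
the window is Poisson distributed with mean COI, and a lysogen forms when at
least two phages infect the same cell:

    p_lys = 1 - exp(-COI) - COI * exp(-COI)

COI is a real-valued Poisson mean, never an integer count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, UsageError

__all__ = [
    "CoinfectionParams",
    "HillFit",
    "mean_coinfections",
    "coi_from_ratio",
    "lysogeny_probability",
    "hill_model",
    "percent_lysogeny_curve",
    "coi_grid",
    "coi_grid_table",
]

#: Valid Hill cooperation orders.
HILL_ORDERS = (1, 2, 3)


def _check_nonnegative_finite(**named):
    for name, value in named.items():
        arr = np.asarray(value, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise DomainError(f"{name} must be finite, got {value!r}")
        if np.any(arr < 0):
            raise DomainError(f"{name} must be nonnegative, got {value!r}")


@dataclass(frozen=True)
class CoinfectionParams:
    """One phage-host pair's biophysical parameters.

    Attributes
    ----------
    phage_conc : float
        Phage concentration P_i, phages/ml.  May be zero.
    bacteria_conc : float
        Bacterial concentration B_i, cells/ml.  Strictly positive.
    adsorption_rate : float
        Adsorption rate constant alpha, ml/h.  Strictly positive.
    commitment_time : float
        Lysogenic commitment time tau, hours.  Strictly positive.
    """

    phage_conc: float
    bacteria_conc: float
    adsorption_rate: float
    commitment_time: float

    def __post_init__(self):
        _check_nonnegative_finite(phage_conc=self.phage_conc)
        for name in ("bacteria_conc", "adsorption_rate", "commitment_time"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise DomainError(f"{name} must be strictly positive and finite, got {value!r}")

    @property
    def coi(self) -> float:
        """Mean coinfections for this parameter set."""
        return mean_coinfections(self.phage_conc, self.adsorption_rate, self.commitment_time)


@dataclass(frozen=True)
class HillFit:
    """Fitted Hill-Langmuir parameters for percent lysogeny vs MOI/COI.

    amplitude (``a``) is the saturation percent in (0, 100]; half_saturation
    (``b``) sets the midpoint; order ``n`` is the cooperation order in
    {1, 2, 3}; residual_sum_squares is in percent squared.
    """

    amplitude: float
    half_saturation: float
    order: int
    residual_sum_squares: float = float("nan")

    def __post_init__(self):
        if not (0 < self.amplitude <= 100):
            raise DomainError(f"amplitude must be in (0, 100], got {self.amplitude!r}")
        if not (self.half_saturation > 0):
            raise DomainError(f"half_saturation must be > 0, got {self.half_saturation!r}")
        if self.order not in HILL_ORDERS:
            raise DomainError(f"order must be one of {HILL_ORDERS}, got {self.order!r}")

    def __call__(self, x, printed_form: bool = False):
        return hill_model(x, self.amplitude, self.half_saturation, self.order,
                          printed_form=printed_form)


def mean_coinfections(phage_conc, adsorption_rate, commitment_time):
    """Mean number of phage infections per cell within the commitment time.

    COI = P_i * alpha * tau.  Exactly linear in each argument.

    Parameters are phages/ml, ml/h and hours; the product is dimensionless.
    Accepts scalars or arrays (broadcast).
    """
    _check_nonnegative_finite(phage_conc=phage_conc, adsorption_rate=adsorption_rate,
                              commitment_time=commitment_time)
    out = np.asarray(phage_conc, dtype=float) * adsorption_rate * commitment_time
    return float(out) if out.ndim == 0 else out


def coi_from_ratio(ratio, bacteria_conc, adsorption_rate, commitment_time):
    """COI expressed through the phage-to-bacterium ratio.

    COI = alpha * tau * B_i * (P_i / B_i); the ratio form is the proxy used to
    compare with MOI experiments where the operational MOI is P0/B0.
    """
    _check_nonnegative_finite(ratio=ratio, bacteria_conc=bacteria_conc)
    return mean_coinfections(np.asarray(ratio, dtype=float) * bacteria_conc,
                             adsorption_rate, commitment_time)


def lysogeny_probability(coi):
    """Probability that a cell is infected by at least two phages.

    p_lys = 1 - e^(-COI) - COI e^(-COI), i.e. P(k >= 2) for k ~ Poisson(COI).
    Strictly increasing on COI > 0 with limit 1; for COI beyond ~700 the
    exponential underflows and the result is exactly 1.0, which is the
    correct limit rather than an artifact.
    """
    arr = np.asarray(coi, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise DomainError(f"coi must be finite, got {coi!r}")
    if np.any(arr < 0):
        raise DomainError(f"coi must be nonnegative, got {coi!r}")
    with np.errstate(under="ignore"):
        e = np.exp(-arr)
        out = -np.expm1(-arr) - arr * e
    out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def hill_model(x, amplitude, half_saturation, order, printed_form: bool = False):
    """Hill-Langmuir percent lysogeny as a function of MOI (or COI).

    The default form is the standard saturating sigmoid

        f(x) = a * x**n / (b + x**n)

    which approaches the amplitude ``a`` at large x.  ``printed_form=True``
    evaluates ``a * x / (b + x**n)`` instead, a variant that does not
    saturate (and decreases at large x) for n >= 2; it is provided because
    both parameterizations appear in the lysogeny-cooperativity literature
    and only the standard form reproduces a sigmoid reaching ~100%.
    """
    if order not in HILL_ORDERS:
        raise DomainError(f"order must be one of {HILL_ORDERS}, got {order!r}")
    _check_nonnegative_finite(x=x)
    if not (half_saturation > 0):
        raise DomainError(f"half_saturation must be > 0, got {half_saturation!r}")
    xa = np.asarray(x, dtype=float)
    num = amplitude * (xa if printed_form else xa ** order)
    out = num / (half_saturation + xa ** order)
    return float(out) if out.ndim == 0 else out


def percent_lysogeny_curve(ratio_grid, bacteria_conc, adsorption_rate, commitment_time):
    """Percent lysogeny along a grid of phage-to-bacterium ratios.

    Element-wise ``100 * p_lys(COI(ratio))``; non-decreasing along any
    non-decreasing grid because both COI and p_lys are monotone.
    """
    coi = coi_from_ratio(np.asarray(ratio_grid, dtype=float), bacteria_conc,
                         adsorption_rate, commitment_time)
    return 100.0 * lysogeny_probability(coi)


#: Axis names accepted by :func:`coi_grid`, mapping to CoinfectionParams fields.
_GRID_AXES = ("bacteria_conc", "adsorption_rate", "commitment_time")


def coi_grid(varying: str, values, ratio_grid, fixed: CoinfectionParams) -> np.ndarray:
    """COI over a cartesian (parameter value, ratio) grid.

    One of ``bacteria_conc``, ``adsorption_rate`` or ``commitment_time`` is
    swept over ``values`` while the other two stay at their values in
    ``fixed``; the phage concentration enters through the ratio.  Returns a
    matrix of shape ``(len(values), len(ratio_grid))``, monotone increasing
    along both axes.  This is the quantitative content of the contour scans
    relating COI to the phage-to-bacterium ratio.
    """
    if varying not in _GRID_AXES:
        raise UsageError(f"varying must be one of {_GRID_AXES}, got {varying!r}")
    values = np.asarray(values, dtype=float)
    ratios = np.asarray(ratio_grid, dtype=float)
    params = {name: getattr(fixed, name) for name in _GRID_AXES}
    out = np.empty((values.size, ratios.size), dtype=float)
    for i, v in enumerate(values):
        params[varying] = v
        out[i, :] = coi_from_ratio(ratios, params["bacteria_conc"],
                                   params["adsorption_rate"], params["commitment_time"])
    return out


def coi_grid_table(varying: str, values, ratio_grid, fixed: CoinfectionParams):
    """Tidy long-format table of a :func:`coi_grid` scan.

    Columns: the varied axis value, the ratio, and COI — the layout used for
    CSV export of grid scans.
    """
    import pandas as pd

    matrix = coi_grid(varying, values, ratio_grid, fixed)
    values = np.asarray(values, dtype=float)
    ratios = np.asarray(ratio_grid, dtype=float)
    return pd.DataFrame({
        varying: np.repeat(values, ratios.size),
        "ratio": np.tile(ratios, values.size),
        "coi": matrix.ravel(),
    })
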
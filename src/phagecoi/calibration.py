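"""Calibration and data-reduction procedures of the meta-analysis.

Covers the empirical scaffolding around the coinfection model: the
phage-vs-bacteria abundance power law, Hill-Langmuir fits to MOI experiments
with cooperation-order selection, rank-abundance curve construction and
consensus averaging, and two-group trait comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .core import HILL_ORDERS, HillFit, hill_model
from .exceptions import DomainError, FitError, UsageError

__all__ = [
    "PowerLawFit",
    "RankAbundanceCurve",
    "GroupComparison",
    "MARINE_POWERLAW",
    "GUT_POWERLAW",
    "fit_power_law",
    "phage_from_bacteria_deterministic",
    "fit_hill",
    "select_hill_order",
    "build_rank_abundance",
    "consensus_rank_abundance",
    "compare_groups",
]


@dataclass(frozen=True)
class PowerLawFit:
    """Power-law relation P(B) = a * (B / B_u)**b between total phage and
    bacterial concentrations.

    prefactor ``a`` is in phages/ml, exponent ``b`` dimensionless and
    ``unit_bacteria`` (B_u) fixes the normalization at 1 cell/ml.
    """

    prefactor: float
    exponent: float
    unit_bacteria: float = 1.0
    r_squared: float = float("nan")

    def __post_init__(self):
        if not (self.prefactor > 0 and np.isfinite(self.prefactor)):
            raise DomainError(f"prefactor must be > 0, got {self.prefactor!r}")
        if not np.isfinite(self.exponent):
            raise DomainError(f"exponent must be finite, got {self.exponent!r}")

    def predict(self, bacteria_conc):
        return phage_from_bacteria_deterministic(bacteria_conc, self)


#: Printed meta-analysis fits: total phage vs total bacterial concentration.
MARINE_POWERLAW = PowerLawFit(prefactor=10 ** 2.50, exponent=0.712)
GUT_POWERLAW = PowerLawFit(prefactor=10 ** 5.35, exponent=0.388)


@dataclass(frozen=True)
class RankAbundanceCurve:
    """Relative abundances of the top R ranks of a phage or bacterial community.

    Frequencies are strictly positive, non-increasing with rank, and sum to
    at most 1 (they are fractions of the whole community, of which the top R
    ranks are only a part).
    """

    frequencies: np.ndarray
    kind: str = "phage"
    ecosystem: str = "marine"

    def __post_init__(self):
        freqs = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", freqs)
        if freqs.ndim != 1 or freqs.size < 1:
            raise UsageError("frequencies must be a nonempty 1-D array")
        if np.any(freqs <= 0):
            raise DomainError("rank frequencies must be strictly positive")
        if np.any(np.diff(freqs) > 0):
            raise DomainError("rank frequencies must be non-increasing with rank")
        total = freqs.sum()
        if total > 1 + 1e-12:
            raise DomainError(
                f"rank frequencies sum to {total:.4f} > 1; the top ranks cannot "
                "exceed the whole community")

    @property
    def n_ranks(self) -> int:
        return int(self.frequencies.size)

    @property
    def rank1(self) -> float:
        return float(self.frequencies[0])


@dataclass(frozen=True)
class GroupComparison:
    """Two-sided Welch t test result on log10-transformed values."""

    statistic: float
    p_value: float
    group_medians: tuple = field(default=(float("nan"), float("nan")))

    def __post_init__(self):
        if not (0 <= self.p_value <= 1):
            raise DomainError(f"p_value must be in [0, 1], got {self.p_value!r}")


def fit_power_law(bacteria_concs, phage_concs) -> PowerLawFit:
    """Least-squares line through the log10-log10 abundance data.

    Fits log10 P = intercept + slope * log10 B and re-expresses the line as
    ``PowerLawFit(prefactor=10**intercept, exponent=slope)``.  Requires at
    least 3 strictly positive pairs with nonzero spread in B.
    """
    b = np.asarray(bacteria_concs, dtype=float)
    p = np.asarray(phage_concs, dtype=float)
    if b.size != p.size:
        raise UsageError("bacteria_concs and phage_concs must have equal length")
    if b.size < 3:
        raise DomainError(f"need at least 3 pairs, got {b.size}")
    if np.any(b <= 0) or np.any(p <= 0):
        raise DomainError("all concentrations must be strictly positive")
    logb, logp = np.log10(b), np.log10(p)
    if np.ptp(logb) == 0:
        raise DomainError("bacterial concentrations have zero variance; slope undefined")
    res = stats.linregress(logb, logp)
    return PowerLawFit(prefactor=10.0 ** res.intercept, exponent=float(res.slope),
                       r_squared=float(res.rvalue ** 2))


def phage_from_bacteria_deterministic(bacteria_conc, fit: PowerLawFit):
    """Noise-free power-law prediction P(B) = a * (B / B_u)**b, phages/ml."""
    b = np.asarray(bacteria_conc, dtype=float)
    if np.any(b <= 0) or not np.all(np.isfinite(b)):
        raise DomainError(f"bacteria_conc must be strictly positive, got {bacteria_conc!r}")
    out = fit.prefactor * (b / fit.unit_bacteria) ** fit.exponent
    return float(out) if out.ndim == 0 else out


def _hill_residuals(x, y, a, b, order, printed_form):
    return y - hill_model(x, a, b, order, printed_form=printed_form)


def fit_hill(x_values, y_values, order: int, printed_form: bool = False,
             n_restarts: int = 8) -> HillFit:
    """Nonlinear least-squares Hill-Langmuir fit at a fixed cooperation order.

    Bounded fit (amplitude in (0, 100], half-saturation > 0) with a small
    multi-start ladder over half-saturation scales; raises :class:`FitError`
    with diagnostics if no start converges.
    """
    if order not in HILL_ORDERS:
        raise DomainError(f"order must be one of {HILL_ORDERS}, got {order!r}")
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.size != y.size:
        raise UsageError("x_values and y_values must have equal length")
    if x.size < 4:
        raise DomainError(f"need at least 4 points, got {x.size}")
    if np.any(x < 0):
        raise DomainError("x_values must be nonnegative")
    if np.any((y < 0) | (y > 100)):
        raise DomainError("y_values must be percentages in [0, 100]")

    def model(xx, a, b):
        return hill_model(xx, a, b, order, printed_form=printed_form)

    a0 = max(float(np.max(y)), 1e-6)
    positive_x = x[x > 0]
    b_scale = float(np.median(positive_x)) ** order if positive_x.size else 1.0
    starts = [(a0, b_scale * 10.0 ** k) for k in np.linspace(-2, 2, n_restarts)]
    best, best_rss, failures = None, np.inf, []
    for a_start, b_start in starts:
        try:
            popt, _ = optimize.curve_fit(
                model, x, y, p0=[a_start, max(b_start, 1e-12)],
                bounds=([1e-9, 1e-12], [100.0, np.inf]), maxfev=20000)
        except (RuntimeError, optimize.OptimizeWarning) as exc:  # no convergence
            failures.append(str(exc))
            continue
        rss = float(np.sum((y - model(x, *popt)) ** 2))
        if rss < best_rss:
            best, best_rss = popt, rss
    if best is None:
        raise FitError(f"Hill fit of order {order} failed to converge",
                       diagnostics={"order": order, "n_points": int(x.size),
                                    "failures": failures})
    return HillFit(amplitude=float(best[0]), half_saturation=float(best[1]),
                   order=order, residual_sum_squares=best_rss)


def select_hill_order(x_values, y_values, printed_form: bool = False):
    """Fit all cooperation orders in {1, 2, 3} and pick the best.

    Returns ``(best_fit, fits)`` where ``fits`` maps each order that
    converged to its :class:`HillFit`.  Selection is by minimal residual sum
    of squares; exact ties go to the lower order (parsimony).  Raises
    :class:`FitError` only if every order fails.
    """
    fits: dict[int, HillFit] = {}
    failures: dict[int, str] = {}
    for order in HILL_ORDERS:
        try:
            fits[order] = fit_hill(x_values, y_values, order, printed_form=printed_form)
        except FitError as exc:
            failures[order] = str(exc)
    if not fits:
        raise FitError("all Hill orders failed to converge", diagnostics=failures)
    min_rss = min(f.residual_sum_squares for f in fits.values())
    # ties (to within optimizer noise) go to the lower order: parsimony
    tol = 1e-9 * max(min_rss, 1e-12)
    best_order = min(o for o, f in fits.items()
                     if f.residual_sum_squares <= min_rss + tol)
    return fits[best_order], fits


def build_rank_abundance(rank1_freq: float, decay_exponent: float, n_ranks: int = 100,
                         kind: str = "phage", ecosystem: str = "marine") -> RankAbundanceCurve:
    """Power-law rank-abundance curve f(r) = rank1_freq * r**(-decay_exponent).

    The rank-1 value is preserved exactly; a parameter combination whose top
    ``n_ranks`` frequencies would sum past 1 is rejected.
    """
    if not (0 < rank1_freq < 1):
        raise DomainError(f"rank1_freq must be in (0, 1), got {rank1_freq!r}")
    if n_ranks < 1:
        raise DomainError(f"n_ranks must be >= 1, got {n_ranks!r}")
    if decay_exponent < 0:
        raise DomainError(f"decay_exponent must be >= 0, got {decay_exponent!r}")
    ranks = np.arange(1, n_ranks + 1, dtype=float)
    freqs = rank1_freq * ranks ** (-decay_exponent)
    return RankAbundanceCurve(frequencies=freqs, kind=kind, ecosystem=ecosystem)


def consensus_rank_abundance(tables, kind: str = "bacteria",
                             ecosystem: str = "marine") -> RankAbundanceCurve:
    """Per-rank arithmetic mean across per-sample frequency vectors.

    Mirrors consensus construction across metagenomes: the frequency of the
    community member at each rank is averaged over samples within an
    ecosystem.  All vectors must share a length; the averaged curve must
    still satisfy the rank-abundance invariants.
    """
    tables = [np.asarray(t, dtype=float) for t in tables]
    if len(tables) == 0:
        raise UsageError("need at least one rank table")
    length = tables[0].size
    if any(t.ndim != 1 or t.size != length for t in tables):
        raise UsageError("all rank tables must be 1-D vectors of equal length")
    if any(np.any(t < 0) for t in tables):
        raise DomainError("rank frequencies must be nonnegative")
    mean = np.mean(np.vstack(tables), axis=0)
    return RankAbundanceCurve(frequencies=mean, kind=kind, ecosystem=ecosystem)


def compare_groups(values_a, values_b) -> GroupComparison:
    """Two-sided Welch t test between two trait groups.

    Rates and abundances span orders of magnitude, so the test operates on
    log10-transformed values; medians are reported in native units.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DomainError("each group needs at least 2 values")
    if np.any(a <= 0) or np.any(b <= 0):
        raise DomainError("values must be strictly positive for the log10 transform")
    la, lb = np.log10(a), np.log10(b)
    res = stats.ttest_ind(la, lb, equal_var=False)
    statistic, p_value = float(res.statistic), float(res.pvalue)
    if np.isnan(statistic) and np.var(la) == 0 and np.var(lb) == 0:
        # both groups constant: equal means -> no evidence; different -> certain
        if np.mean(la) == np.mean(lb):
            statistic, p_value = 0.0, 1.0
        else:
            statistic = np.inf if np.mean(la) > np.mean(lb) else -np.inf
            p_value = 0.0
    return GroupComparison(statistic=statistic, p_value=p_value,
                           group_medians=(float(np.median(a)), float(np.median(b))))
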
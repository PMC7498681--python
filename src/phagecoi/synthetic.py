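"""Synthetic fixture generators for every pipeline stage.

The meta-analysis behind the community model rests on literature trait
tables (adsorption rates, duplication times, particle and cell counts),
per-sample rank-abundance tables from viromes/metagenomes, and lambda MOI
experiments.  The generators here emulate the *statistical structure* of
those inputs — log-uniform trait spreads within the printed ranges,
power-law abundance coupling with log-space noise, power-law rank decay
with multiplicative noise, Hill-shaped lysogeny-vs-MOI curves with binomial
counting noise — so calibration and simulation can be exercised end to end
with no external data.  No claim is made that real supplementary data
follow these exact laws; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import PowerLawFit, RankAbundanceCurve
from .core import HILL_ORDERS, hill_model
from .exceptions import DomainError, UsageError

__all__ = [
    "TRAIT_RANGES",
    "MoiExperiment",
    "gen_trait_records",
    "gen_abundance_pairs",
    "gen_rank_tables",
    "gen_moi_experiment",
]

#: Printed meta-analysis ranges per (kind, ecosystem), native units.
#: Marine duplication times are commitment range / 0.2.
TRAIT_RANGES = {
    ("adsorption", "marine"): (7.2e-10, 3.7e-7),
    ("adsorption", "gut"): (5.9e-8, 1.2e-6),
    ("duplication", "marine"): (55.0, 4040.0),
    ("duplication", "gut"): (2.74, 7.27),
    ("vlp_count", "marine"): (1.45e5, 3.80e7),
    ("vlp_count", "gut"): (5.09e6, 1.05e10),
    ("cell_count", "marine"): (3.78e4, 6.75e6),
    ("cell_count", "gut"): (3.45e5, 7.60e9),
}

_TAXA = {
    "marine": ["Prochlorococcus sp.", "Synechococcus sp.", "Vibrio sp.",
               "Roseobacter sp.", "Pseudoalteromonas sp."],
    "gut": ["Escherichia coli", "Bacteroides sp.", "Faecalibacterium sp."],
}


@dataclass(frozen=True)
class MoiExperiment:
    """A synthetic lysogenization-vs-MOI experiment.

    Per MOI level: number of cells assayed and number observed to become
    lysogens, drawn binomially from a Hill-Langmuir generating curve whose
    parameters are recorded for recovery tests.
    """

    moi_levels: np.ndarray
    cells_assayed: np.ndarray
    lysogens_observed: np.ndarray
    amplitude: float
    half_saturation: float
    order: int

    def __post_init__(self):
        if np.any(self.lysogens_observed > self.cells_assayed):
            raise DomainError("lysogens_observed cannot exceed cells_assayed")

    @property
    def percent_lysogeny(self) -> np.ndarray:
        return 100.0 * self.lysogens_observed / self.cells_assayed

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "moi": self.moi_levels,
            "cells_assayed": self.cells_assayed,
            "lysogens_observed": self.lysogens_observed,
            "percent_lysogeny": self.percent_lysogeny,
        })


def _loguniform(lo: float, hi: float, n: int, rng: np.random.Generator) -> np.ndarray:
    return 10.0 ** rng.uniform(np.log10(lo), np.log10(hi), size=n)


def gen_trait_records(kind: str, ecosystem: str, n: int,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Log-uniform trait records within the printed range for (kind, ecosystem).

    Returns a table with columns ecosystem, host_taxon, kind, value —
    the shape consumed by :func:`phagecoi.calibration.compare_groups`.
    """
    key = (kind, ecosystem)
    if key not in TRAIT_RANGES:
        raise UsageError(f"unknown (kind, ecosystem) combination {key!r}; "
                         f"valid: {sorted(TRAIT_RANGES)}")
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n}")
    lo, hi = TRAIT_RANGES[key]
    values = _loguniform(lo, hi, n, rng)
    taxa = rng.choice(_TAXA[ecosystem], size=n)
    return pd.DataFrame({"ecosystem": ecosystem, "host_taxon": taxa,
                         "kind": kind, "value": values})


def gen_abundance_pairs(powerlaw: PowerLawFit, noise_sd_dex: float, n: int,
                        rng: np.random.Generator,
                        bacteria_range=(1e4, 1e10)) -> pd.DataFrame:
    """(bacteria, phage) abundance pairs scattered around a power law.

    B is log-uniform over ``bacteria_range``; P = P(B) * 10**N(0, noise_sd_dex).
    With zero noise, :func:`phagecoi.calibration.fit_power_law` recovers the
    generator exactly.
    """
    if n < 3:
        raise DomainError(f"need n >= 3 for downstream fitting, got {n}")
    bacteria = _loguniform(bacteria_range[0], bacteria_range[1], n, rng)
    log_p = np.log10(powerlaw.predict(bacteria)) + rng.normal(0.0, noise_sd_dex, size=n)
    return pd.DataFrame({"bacteria_conc": bacteria, "phage_conc": 10.0 ** log_p})


def gen_rank_tables(curve: RankAbundanceCurve, n_samples: int, noise_sd_dex: float,
                    rng: np.random.Generator) -> list[np.ndarray]:
    """Per-sample rank-frequency vectors scattered around a consensus curve.

    Each sample is the input curve with multiplicative log-normal noise
    (SD ``noise_sd_dex`` in log10), re-sorted non-increasing so every sample
    is itself a valid rank-abundance vector.
    """
    if n_samples < 1:
        raise DomainError(f"n_samples must be >= 1, got {n_samples}")
    base = np.log10(curve.frequencies)
    tables = []
    for _ in range(n_samples):
        noisy = 10.0 ** (base + rng.normal(0.0, noise_sd_dex, size=base.size))
        tables.append(np.sort(noisy)[::-1])
    return tables


def gen_moi_experiment(amplitude: float, half_saturation: float, order: int,
                       moi_levels, cells_per_level: int,
                       rng: np.random.Generator) -> MoiExperiment:
    """Binomially noised lysogenization counts from a Hill generating curve.

    Per MOI level, ``cells_per_level`` cells are assayed and each becomes a
    lysogen with probability hill(moi)/100.  ``amplitude`` may be 0 to
    generate an all-negative control experiment.
    """
    if order not in HILL_ORDERS:
        raise DomainError(f"order must be one of {HILL_ORDERS}, got {order!r}")
    if cells_per_level < 1:
        raise DomainError(f"cells_per_level must be >= 1, got {cells_per_level}")
    moi = np.asarray(moi_levels, dtype=float)
    if amplitude == 0:
        probs = np.zeros_like(moi)
    else:
        probs = hill_model(moi, amplitude, half_saturation, order) / 100.0
    cells = np.full(moi.shape, int(cells_per_level))
    lysogens = rng.binomial(cells, probs)
    return MoiExperiment(moi_levels=moi, cells_assayed=cells,
                         lysogens_observed=lysogens, amplitude=float(amplitude),
                         half_saturation=float(half_saturation), order=int(order))
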
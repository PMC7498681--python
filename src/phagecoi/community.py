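"""Stochastic community simulation of coinfection-driven lysogeny.

Each simulated community is one point in trait space: a total bacterial
concentration B, an adsorption rate constant alpha and a time parameter,
drawn by Latin hypercube sampling over log10-scaled empirical ranges.  The
total phage concentration P follows the ecosystem's phage-vs-bacteria power
law with multiplicative log-space noise, clamped to the empirical phage
range.  Community structure enters through rank-abundance curves: the phage
of rank i infects the bacterium of rank i (identity infection network), with
per-rank concentrations P_i = P * f_P(i) and B_i = B * f_B(i).  The
coinfection model is applied independently to each of the top ranks and the
resulting lysogens are pooled.

Time semantics differ between the two preset ecosystems.  Marine duplication
data are long enough that the sampled range (11-808 h) is used directly as
the lysogenic commitment time tau; gut data are duplication times
(2.74-7.27 h) and tau = 0.2 x duplication, the commitment fraction measured
in lambda single-cell experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .calibration import (GUT_POWERLAW, MARINE_POWERLAW, PowerLawFit,
                          RankAbundanceCurve, build_rank_abundance)
from .core import lysogeny_probability, mean_coinfections
from .exceptions import DomainError, UsageError

__all__ = [
    "EcosystemConfig",
    "CommunitySample",
    "CommunityResult",
    "marine_config",
    "gut_config",
    "latin_hypercube",
    "phage_from_bacteria",
    "assemble_community",
    "evaluate_community",
    "simulate_ecosystem",
    "daily_lysogen_production",
]

#: Default fraction of the host duplication time available for the
#: lysis/lysogeny decision (lambda single-cell estimate).
COMMITMENT_FRACTION = 0.2

#: Human colon volume used for daily lysogen production, ml.
COLON_VOLUME_ML = 400.0

# Named substream identifiers mixed with the master seed so each random
# purpose has an independent, reproducible stream.
_LHS_STREAM = 0x1A75
_NOISE_STREAM = 0x2B86


@dataclass(frozen=True)
class EcosystemConfig:
    """All parameter ranges and structural settings for one ecosystem.

    Ranges are (min, max) in native units: bacteria cells/ml, phages
    phages/ml, adsorption ml/h, time hours.  ``time_kind`` states whether
    ``time_range`` holds commitment times directly ("commitment") or host
    duplication times ("duplication", with tau = commitment_fraction x
    duplication).  ``noise_sd`` is the SD of the Normal(1, sd) multiplier
    applied to log10 P(B).
    """

    name: str
    bacteria_range: tuple
    phage_range: tuple
    adsorption_range: tuple
    time_range: tuple
    time_kind: str
    powerlaw: PowerLawFit
    phage_curve: RankAbundanceCurve
    bacteria_curve: RankAbundanceCurve
    commitment_fraction: float = COMMITMENT_FRACTION
    noise_sd: float = 0.05
    colon_volume_ml: float | None = None

    def __post_init__(self):
        for rname in ("bacteria_range", "phage_range", "adsorption_range", "time_range"):
            lo, hi = getattr(self, rname)
            if not (0 < lo < hi and np.isfinite(hi)):
                raise DomainError(f"{rname} must satisfy 0 < min < max, got {(lo, hi)!r}")
        if self.time_kind not in ("commitment", "duplication"):
            raise UsageError(f"time_kind must be 'commitment' or 'duplication', "
                             f"got {self.time_kind!r}")
        if not (0 < self.commitment_fraction <= 1):
            raise DomainError("commitment_fraction must be in (0, 1]")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be >= 0")
        if self.phage_curve.n_ranks != self.bacteria_curve.n_ranks:
            raise UsageError("phage and bacteria curves must have equal rank counts")

    @property
    def n_ranks(self) -> int:
        return self.phage_curve.n_ranks

    def with_overrides(self, **kwargs) -> "EcosystemConfig":
        return replace(self, **kwargs)


def marine_config(n_ranks: int = 100, phage_decay: float = 0.8,
                  bacteria_decay: float = 1.0, **overrides) -> EcosystemConfig:
    """Surface-ocean defaults from the marine meta-analysis.

    B 3.78e4-6.75e6 cells/ml, P 1.45e5-3.80e7 phages/ml (clamp bounds),
    alpha 7.2e-10-3.7e-7 ml/h, commitment time 11-808 h sampled directly.
    Rank-1 relative abundances: phage 0.8%, bacteria 19%.
    """
    cfg = EcosystemConfig(
        name="marine",
        bacteria_range=(3.78e4, 6.75e6),
        phage_range=(1.45e5, 3.80e7),
        adsorption_range=(7.2e-10, 3.7e-7),
        time_range=(11.0, 808.0),
        time_kind="commitment",
        powerlaw=MARINE_POWERLAW,
        phage_curve=build_rank_abundance(0.008, phage_decay, n_ranks,
                                         kind="phage", ecosystem="marine"),
        bacteria_curve=build_rank_abundance(0.19, bacteria_decay, n_ranks,
                                            kind="bacteria", ecosystem="marine"),
    )
    return cfg.with_overrides(**overrides) if overrides else cfg


def gut_config(n_ranks: int = 100, phage_decay: float = 0.8,
               bacteria_decay: float = 1.0, **overrides) -> EcosystemConfig:
    """Mammalian-gut defaults from the gut meta-analysis.

    B 3.45e5-7.60e9 cells/ml, P 5.09e6-1.05e10 phages/ml (clamp bounds),
    alpha 5.9e-8-1.2e-6 ml/h, duplication time 2.74-7.27 h with
    tau = 0.2 x duplication.  Rank-1 relative abundances: phage 1%
    ("just over 1%" in the meta-analysis), bacteria 15%.
    """
    cfg = EcosystemConfig(
        name="gut",
        bacteria_range=(3.45e5, 7.60e9),
        phage_range=(5.09e6, 1.05e10),
        adsorption_range=(5.9e-8, 1.2e-6),
        time_range=(2.74, 7.27),
        time_kind="duplication",
        powerlaw=GUT_POWERLAW,
        phage_curve=build_rank_abundance(0.01, phage_decay, n_ranks,
                                         kind="phage", ecosystem="gut"),
        bacteria_curve=build_rank_abundance(0.15, bacteria_decay, n_ranks,
                                            kind="bacteria", ecosystem="gut"),
        colon_volume_ml=COLON_VOLUME_ML,
    )
    return cfg.with_overrides(**overrides) if overrides else cfg


@dataclass(frozen=True)
class CommunitySample:
    """One sampled community's traits before model evaluation."""

    bacteria_total: float
    phage_total: float
    adsorption_rate: float
    commitment_time: float
    duplication_time: float
    ecosystem: str = ""
    sample_index: int = 0
    seed_provenance: tuple = ()


@dataclass(frozen=True)
class CommunityResult:
    """Per-rank and total outputs of the coinfection model for one community."""

    sample: CommunitySample
    phage_conc: np.ndarray
    bacteria_conc: np.ndarray
    coi: np.ndarray
    p_lys: np.ndarray
    lysogen_conc: np.ndarray
    total_lysogen_conc: float
    percent_lysogeny: float
    vmr: float
    rank_contributions: np.ndarray = field(default=None)


def latin_hypercube(ranges, n_samples: int, master_seed: int) -> np.ndarray:
    """Latin hypercube draw over log10-scaled ranges, returned in native units.

    Each dimension's log10 range is split into ``n_samples`` equal strata;
    every stratum contributes exactly one uniform draw, and strata are
    permuted independently across dimensions.  Shape: (n_samples, n_dims).
    """
    ranges = [tuple(map(float, r)) for r in ranges]
    for lo, hi in ranges:
        if not (0 < lo < hi and np.isfinite(hi)):
            raise DomainError(f"invalid range {(lo, hi)!r}: need 0 < min < max")
    if n_samples < 1:
        raise DomainError(f"n_samples must be >= 1, got {n_samples}")
    seed = np.random.SeedSequence([int(master_seed), _LHS_STREAM])
    sampler = qmc.LatinHypercube(d=len(ranges), seed=np.random.default_rng(seed))
    unit = sampler.random(n=n_samples)
    lows = np.log10([r[0] for r in ranges])
    highs = np.log10([r[1] for r in ranges])
    return 10.0 ** (lows + unit * (highs - lows))


def phage_from_bacteria(bacteria_conc, config: EcosystemConfig, rng: np.random.Generator):
    """Total phage concentration from the power law with log-space noise.

    log10 P = N(1, noise_sd) * log10 P(B), then clamped into the ecosystem's
    empirical phage range.  The multiplier acts on the log10 value itself,
    so the absolute noise grows with magnitude.  Accepts scalar or array B.
    """
    b = np.asarray(bacteria_conc, dtype=float)
    if np.any(b <= 0):
        raise DomainError("bacteria_conc must be strictly positive")
    log_p = np.log10(config.powerlaw.predict(b))
    factor = rng.normal(loc=1.0, scale=config.noise_sd, size=b.shape)
    p = 10.0 ** (factor * log_p)
    out = np.clip(p, config.phage_range[0], config.phage_range[1])
    return float(out) if out.ndim == 0 else out


def _derive_times(time_value, config: EcosystemConfig):
    """(commitment_time, duplication_time) from the sampled time parameter."""
    t = np.asarray(time_value, dtype=float)
    if config.time_kind == "duplication":
        return config.commitment_fraction * t, t
    return t, t / config.commitment_fraction


def assemble_community(raw_sample, config: EcosystemConfig,
                       rng: np.random.Generator, sample_index: int = 0,
                       master_seed: int | None = None) -> CommunitySample:
    """Turn one raw LHS draw (B, alpha, time) into a full community sample.

    Applies the phage power law with noise and clamping, and resolves the
    commitment/duplication time pair according to the ecosystem's time kind.
    """
    bacteria, adsorption, time_value = map(float, raw_sample)
    tau, duplication = _derive_times(time_value, config)
    phage = float(phage_from_bacteria(bacteria, config, rng))
    provenance = (master_seed, sample_index) if master_seed is not None else ()
    return CommunitySample(
        bacteria_total=bacteria, phage_total=phage, adsorption_rate=adsorption,
        commitment_time=float(tau), duplication_time=float(duplication),
        ecosystem=config.name, sample_index=sample_index,
        seed_provenance=provenance)


def evaluate_community(sample: CommunitySample, config: EcosystemConfig) -> CommunityResult:
    """Apply the coinfection model rank by rank and pool the lysogens.

    P_i = P * f_P(i), B_i = B * f_B(i); COI_i = P_i * alpha * tau; p_lys,i
    from the Poisson coinfection model; lysogen concentration B_i * p_lys,i.
    Percent lysogeny uses the *total* bacterial concentration B as the
    denominator (the top ranks are a subset of the community), so it can
    never exceed 100 x sum(f_B).
    """
    f_p = config.phage_curve.frequencies
    f_b = config.bacteria_curve.frequencies
    phage_i = sample.phage_total * f_p
    bacteria_i = sample.bacteria_total * f_b
    coi = mean_coinfections(phage_i, sample.adsorption_rate, sample.commitment_time)
    p_lys = lysogeny_probability(coi)
    lysogens = bacteria_i * p_lys
    total = float(lysogens.sum())
    percent = 100.0 * total / sample.bacteria_total
    contributions = lysogens / total if total > 0 else np.zeros_like(lysogens)
    return CommunityResult(
        sample=sample, phage_conc=phage_i, bacteria_conc=bacteria_i, coi=coi,
        p_lys=p_lys, lysogen_conc=lysogens, total_lysogen_conc=total,
        percent_lysogeny=percent, vmr=sample.phage_total / sample.bacteria_total,
        rank_contributions=contributions)


#: Number of leading ranks whose COI and lysogen contribution are reported
#: as individual columns in the simulation table.
_REPORT_RANKS = 3


def simulate_ecosystem(config: EcosystemConfig, n_communities: int = 100_000,
                       master_seed: int = 0) -> pd.DataFrame:
    """Simulate ``n_communities`` stochastic communities for one ecosystem.

    Fully vectorized: LHS over (B, alpha, time) in log10 space, phage power
    law with Normal(1, noise_sd) log-space noise and clamping, then the
    per-rank coinfection model.  Reproducible from ``master_seed``; the
    i-th community always consumes the i-th element of each named random
    stream, so results do not depend on evaluation order.

    Returns one row per community with columns: ecosystem, sample_index,
    bacteria_conc, phage_conc, adsorption_rate, commitment_time,
    duplication_time, coi_rank1..3, percent_lysogeny, lysogen_conc, vmr,
    contribution_rank1..3.
    """
    if n_communities < 1:
        raise DomainError(f"n_communities must be >= 1, got {n_communities}")
    raw = latin_hypercube(
        [config.bacteria_range, config.adsorption_range, config.time_range],
        n_communities, master_seed)
    bacteria, adsorption, time_value = raw[:, 0], raw[:, 1], raw[:, 2]
    tau, duplication = _derive_times(time_value, config)

    noise_rng = np.random.default_rng(
        np.random.SeedSequence([int(master_seed), _NOISE_STREAM]))
    phage = phage_from_bacteria(bacteria, config, noise_rng)

    f_p = config.phage_curve.frequencies
    f_b = config.bacteria_curve.frequencies
    # (n, ranks) COI matrix; per-community alpha*tau shared by all ranks
    per_cell = phage * adsorption * tau
    coi = per_cell[:, None] * f_p[None, :]
    p_lys = lysogeny_probability(coi)
    weighted = p_lys * f_b[None, :]                 # lysogen fraction of B per rank
    frac_total = weighted.sum(axis=1)
    lysogen_conc = bacteria * frac_total
    percent = 100.0 * frac_total
    with np.errstate(invalid="ignore", divide="ignore"):
        contributions = np.where(frac_total[:, None] > 0,
                                 weighted / frac_total[:, None], 0.0)

    out = {
        "ecosystem": config.name,
        "sample_index": np.arange(n_communities),
        "bacteria_conc": bacteria,
        "phage_conc": phage,
        "adsorption_rate": adsorption,
        "commitment_time": np.broadcast_to(tau, bacteria.shape).copy(),
        "duplication_time": np.broadcast_to(duplication, bacteria.shape).copy(),
    }
    for r in range(min(_REPORT_RANKS, config.n_ranks)):
        out[f"coi_rank{r + 1}"] = coi[:, r]
    out["percent_lysogeny"] = percent
    out["lysogen_conc"] = lysogen_conc
    out["vmr"] = phage / bacteria
    for r in range(min(_REPORT_RANKS, config.n_ranks)):
        out[f"contribution_rank{r + 1}"] = contributions[:, r]
    return pd.DataFrame(out)


def daily_lysogen_production(percent_lysogeny: float, bacteria_conc: float,
                             volume_ml: float, duplication_time_h: float) -> float:
    """Lysogens formed per day in a habitat of the given volume.

    Standing stock of lysogens (percent/100 x B x V) times the daily
    turnover of the bacterial community (24 h / duplication time).  With the
    gut medians (47.8%, 1.7e9 cells/ml, 400 ml, 4.75 h) this yields ~1.6e12
    lysogens per day.
    """
    if duplication_time_h <= 0:
        raise DomainError("duplication_time_h must be positive")
    if bacteria_conc < 0 or volume_ml < 0 or percent_lysogeny < 0:
        raise DomainError("inputs must be nonnegative")
    return (percent_lysogeny / 100.0) * bacteria_conc * volume_ml * (24.0 / duplication_time_h)
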
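"""Synthetic circadian cohort generator.

Emulates population-level expression data in which each sample was collected
at an unknown internal circadian phase. Per gene g and sample s,

    x_{g,s} = m_g * (1 + (1 - delta) * A_g * cos(theta_s + eps_{g,s} - phi_g)) * eta_{g,s}

with mesor m_g > 0, relative amplitude A_g, acrophase phi_g, latent sample
phase theta_s drawn from a uniform (or truncated) circular distribution,
per-cell phase jitter eps with SD kappa_inv * (1 + 2*delta), and
multiplicative log-normal noise eta with linear-scale CV sigma. The
disruption factor delta in [0, 1] both suppresses oscillation amplitude and
inflates phase decoherence, so that an intact cohort (delta=0) shows
coherent clock-gene covariation while a disrupted one (delta near 1)
collapses both relative amplitude and cross-gene correlation. Negative
values (possible when (1-delta)*A_g > 1) are clipped to zero.

A time-stamped longitudinal design (replicates every few hours across
multiple days, converted to phase via theta = 2*pi*(t mod 24)/24) is also
provided for validating ordering methods against known collection times.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from ._circular import TWO_PI, wrap
from .preprocess_io import ExpressionMatrix

__all__ = [
    "GeneSpec",
    "SimConfig",
    "SimulatedDataset",
    "default_clock_phase_map",
    "simulate_population",
    "simulate_timecourse",
    "make_reference_correlation",
]


class GeneSpec(NamedTuple):
    """One rhythmic gene: symbol, mesor (linear units), relative amplitude,
    acrophase (radians in [0, 2*pi))."""

    symbol: str
    mesor: float
    ramp: float
    acrophase: float


class ConfigurationError(ValueError):
    pass


# Canonical mammalian core-clock phase map, anchored at ARNTL (BMAL1) = 0.
# Phases are expressed as radians after the ARNTL peak (2*pi = 24 h).
# Ordering follows the standard transcription-translation feedback loop:
# the activators ARNTL/NPAS2/CLOCK peak together; the ROR/REV-ERB loop and
# the PAR-bZip outputs (DBP/TEF/HLF) follow in mid-cycle; the repressors
# (PER/CRY and the BHLHE paralogs) peak roughly in antiphase to ARNTL;
# CRY1/RORC/NFIL3 trail into the late cycle. Mesors and relative amplitudes
# are representative bulk-tissue magnitudes (CLOCK is famously flat, DBP and
# NR1D1 are the highest-amplitude transcripts), with relative amplitude
# capped at 1 so the multiplicative model stays non-negative without
# clipping.
_DEFAULT_CLOCK_MAP = (
    GeneSpec("ARNTL", 150.0, 0.80, 0.00),
    GeneSpec("NPAS2", 60.0, 0.60, 0.30),
    GeneSpec("CLOCK", 120.0, 0.15, 0.40),
    GeneSpec("NR1D1", 90.0, 1.00, 1.60),
    GeneSpec("NR1D2", 80.0, 0.90, 1.80),
    GeneSpec("DBP", 200.0, 1.00, 2.70),
    GeneSpec("TEF", 110.0, 0.70, 2.80),
    GeneSpec("HLF", 70.0, 0.50, 2.90),
    GeneSpec("PER3", 60.0, 0.90, 2.90),
    GeneSpec("PER1", 130.0, 0.70, 3.00),
    GeneSpec("BHLHE40", 140.0, 0.50, 3.10),
    GeneSpec("CRY2", 110.0, 0.40, 3.40),
    GeneSpec("BHLHE41", 50.0, 0.50, 3.50),
    GeneSpec("PER2", 100.0, 0.60, 3.60),
    GeneSpec("CRY1", 90.0, 0.50, 4.70),
    GeneSpec("RORC", 40.0, 0.40, 4.90),
    GeneSpec("NFIL3", 30.0, 0.40, 5.50),
)


def default_clock_phase_map() -> list:
    """Canonical 17-gene core-clock map (ARNTL anchored at phase 0).

    The values are documented package constants representing the canonical
    mammalian clock geometry, not estimates from any particular dataset.
    """
    return [GeneSpec(*g) for g in _DEFAULT_CLOCK_MAP]


@dataclass
class SimConfig:
    """Configuration for a synthetic circadian cohort.

    Parameters
    ----------
    n_samples : cohort size.
    n_genes : total genes; clock genes + background rhythmic genes are
        carved out of this total, the remainder are flat (A=0).
    clock_gene_map : list of GeneSpec (or 4-tuples).
    n_background_rhythmic : number of non-clock rhythmic genes with random
        acrophases and amplitudes.
    phase_distribution : "uniform" or ("truncated", start, end) restricting
        latent phases to a window on [0, 2*pi) (emulating daytime-only
        specimen collection).
    disruption : delta in [0, 1]; 0 = intact clock, 1 = fully arrhythmic.
    phase_decoherence : baseline per-gene, per-sample phase jitter SD
        (radians); effective SD is phase_decoherence * (1 + 2*disruption).
    noise_cv : linear-scale coefficient of variation of the multiplicative
        log-normal noise.
    batches : list of (label, fraction, log_offset); fractions must sum
        to 1. log_offset is a natural-log multiplicative offset.
    seed : mandatory integer RNG seed.
    """

    n_samples: int = 100
    n_genes: int = 1000
    clock_gene_map: Sequence = field(default_factory=default_clock_phase_map)
    n_background_rhythmic: int = 100
    phase_distribution: object = "uniform"
    disruption: float = 0.0
    phase_decoherence: float = 0.0
    noise_cv: float = 0.2
    batches: Sequence = field(default_factory=lambda: [("batch0", 1.0, 0.0)])
    seed: int = 0

    # background-gene priors (log-normal mesors; uniform amplitudes)
    background_ramp_range: tuple = (0.1, 1.0)
    background_mesor_log_mean: float = float(np.log(50.0))
    background_mesor_log_sd: float = 1.0

    def __post_init__(self):
        self.clock_gene_map = [GeneSpec(*g) for g in self.clock_gene_map]
        if self.n_samples < 1 or self.n_genes < 1:
            raise ConfigurationError("n_samples and n_genes must be positive")
        for g in self.clock_gene_map:
            if g.mesor <= 0:
                raise ConfigurationError(f"non-positive mesor for {g.symbol!r}")
            if not (0.0 <= g.ramp <= 1.5):
                raise ConfigurationError(f"relative amplitude of {g.symbol!r} outside [0, 1.5]")
        if not (0.0 <= self.disruption <= 1.0):
            raise ConfigurationError("disruption must lie in [0, 1]")
        if self.phase_decoherence < 0:
            raise ConfigurationError("phase_decoherence must be >= 0")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")
        total = len(self.clock_gene_map) + self.n_background_rhythmic
        if total > self.n_genes:
            raise ConfigurationError(
                f"n_genes={self.n_genes} smaller than clock + background rhythmic genes ({total})"
            )
        fracs = [b[1] for b in self.batches]
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ConfigurationError("batch fractions must sum to 1")
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")
        kind = self.phase_distribution
        if kind != "uniform":
            if not (isinstance(kind, (tuple, list)) and len(kind) == 3 and kind[0] == "truncated"):
                raise ConfigurationError(
                    "phase_distribution must be 'uniform' or ('truncated', start, end)"
                )

    # --- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["clock_gene_map"] = [list(g) for g in self.clock_gene_map]
        d["batches"] = [list(b) for b in self.batches]
        if isinstance(self.phase_distribution, (tuple, list)):
            d["phase_distribution"] = list(self.phase_distribution)
        d["background_ramp_range"] = list(self.background_ramp_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "phase_distribution" in d and isinstance(d["phase_distribution"], list):
            d["phase_distribution"] = tuple(d["phase_distribution"])
        if "background_ramp_range" in d:
            d["background_ramp_range"] = tuple(d["background_ramp_range"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SimulatedDataset:
    """Expression matrix plus full generative ground truth."""

    matrix: ExpressionMatrix
    truth_phases: pd.Series          # sample -> theta in [0, 2*pi)
    truth_gene_params: pd.DataFrame  # gene -> mesor, effective_ramp, acrophase, is_rhythmic
    config: SimConfig

    def __post_init__(self):
        assert len(self.truth_phases) == len(self.matrix.samples)

    def write(self, expr_path, metadata_path=None, truth_path=None) -> None:
        from .preprocess_io import write_expression_tsv

        write_expression_tsv(self.matrix, expr_path, metadata_path)
        if truth_path is not None:
            out = self.truth_phases.rename("theta").to_frame()
            out.index.name = "sample"
            out.to_csv(truth_path, sep="\t")


def _draw_phases(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_samples
    if config.phase_distribution == "uniform":
        return rng.uniform(0.0, TWO_PI, size=n)
    _, start, end = config.phase_distribution
    start, end = wrap(start), wrap(end)
    # rejection sampling from the circular window (window may wrap past 2*pi)
    out = np.empty(0)
    while out.size < n:
        draw = rng.uniform(0.0, TWO_PI, size=4 * n)
        if start <= end:
            ok = (draw >= start) & (draw <= end)
        else:
            ok = (draw >= start) | (draw <= end)
        out = np.concatenate([out, draw[ok]])
    return out[:n]


def _gene_params(config: SimConfig, rng: np.random.Generator):
    """Assemble per-gene (symbol, mesor, ramp, acrophase, is_rhythmic).

    Draw order is fixed and independent of parameter values so that editing
    one gene's mesor never perturbs any other gene's draws.
    """
    clock = config.clock_gene_map
    n_clock = len(clock)
    n_bg = config.n_background_rhythmic
    n_flat = config.n_genes - n_clock - n_bg

    symbols = [g.symbol for g in clock]
    mesor = np.array([g.mesor for g in clock])
    ramp = np.array([g.ramp for g in clock])
    phase = np.array([g.acrophase for g in clock])

    lo, hi = config.background_ramp_range
    bg_mesor = np.exp(rng.normal(config.background_mesor_log_mean,
                                 config.background_mesor_log_sd, size=n_bg))
    bg_ramp = rng.uniform(lo, hi, size=n_bg)
    bg_phase = rng.uniform(0.0, TWO_PI, size=n_bg)
    flat_mesor = np.exp(rng.normal(config.background_mesor_log_mean,
                                   config.background_mesor_log_sd, size=n_flat))

    symbols += [f"RHY{i:04d}" for i in range(n_bg)]
    symbols += [f"FLAT{i:04d}" for i in range(n_flat)]
    mesor = np.concatenate([mesor, bg_mesor, flat_mesor])
    ramp = np.concatenate([ramp, bg_ramp, np.zeros(n_flat)])
    phase = np.concatenate([phase, bg_phase, np.zeros(n_flat)])
    is_rhythmic = ramp > 0
    return symbols, mesor, ramp, phase, is_rhythmic


def _generate(config: SimConfig, theta: np.ndarray, rng: np.random.Generator,
              sample_ids, time_h=None) -> SimulatedDataset:
    symbols, mesor, ramp, phase, is_rhythmic = _gene_params(config, rng)
    n_genes, n_samples = len(symbols), len(theta)
    delta = config.disruption

    jitter_sd = config.phase_decoherence * (1.0 + 2.0 * delta)
    eps = rng.normal(0.0, 1.0, size=(n_genes, n_samples)) * jitter_sd

    sigma = config.noise_cv
    if sigma > 0:
        s_log = np.sqrt(np.log1p(sigma ** 2))
        eta = np.exp(rng.normal(0.0, 1.0, size=(n_genes, n_samples)) * s_log - 0.5 * s_log ** 2)
    else:
        eta = np.ones((n_genes, n_samples))

    labels = [b[0] for b in config.batches]
    fracs = np.array([b[1] for b in config.batches], dtype=float)
    offsets = np.array([b[2] for b in config.batches], dtype=float)
    batch_idx = rng.choice(len(labels), size=n_samples, p=fracs / fracs.sum())
    batch_factor = np.exp(offsets[batch_idx])

    osc = 1.0 + (1.0 - delta) * ramp[:, None] * np.cos(theta[None, :] + eps - phase[:, None])
    x = mesor[:, None] * osc * eta * batch_factor[None, :]
    x = np.maximum(x, 0.0)

    values = pd.DataFrame(x, index=pd.Index(symbols, name="gene"), columns=sample_ids)
    metadata = pd.DataFrame({
        "batch": [labels[i] for i in batch_idx],
        "condition": "simulated",
    }, index=sample_ids)
    if time_h is not None:
        metadata["time_h"] = time_h
    matrix = ExpressionMatrix(values, metadata)
    truth_phases = pd.Series(wrap(theta), index=sample_ids, name="theta")
    truth = pd.DataFrame({
        "mesor": mesor,
        "effective_ramp": (1.0 - delta) * ramp,
        "acrophase": wrap(phase),
        "is_rhythmic": is_rhythmic,
    }, index=values.index)
    return SimulatedDataset(matrix, truth_phases, truth, config)


def simulate_population(config: SimConfig) -> SimulatedDataset:
    """Simulate a cohort with latent (unknown) sample phases.

    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    theta = _draw_phases(config, rng)
    ids = [f"S{i:04d}" for i in range(config.n_samples)]
    return _generate(config, theta, rng, ids)


def simulate_timecourse(config: SimConfig, interval_h: float, duration_h: float,
                        replicates: int) -> SimulatedDataset:
    """Simulate a time-stamped design: ``replicates`` samples at each
    timepoint 0, interval_h, ..., duration_h - interval_h.

    Phases follow theta = 2*pi*(t mod 24)/24; collection times are stored
    in sample metadata (column ``time_h``). ``config.n_samples`` is ignored
    in favour of the design size.
    """
    if replicates < 1:
        raise ConfigurationError("replicates must be >= 1")
    n_points = duration_h / interval_h
    if abs(n_points - round(n_points)) > 1e-9:
        raise ConfigurationError("interval_h must divide duration_h")
    times = np.repeat(np.arange(0.0, duration_h, interval_h), replicates)
    theta = TWO_PI * np.mod(times, 24.0) / 24.0
    config = dataclasses.replace(config, n_samples=len(times))
    rng = np.random.default_rng(config.seed)
    ids = [f"T{t:05.1f}R{r}" for t in np.arange(0.0, duration_h, interval_h)
           for r in range(replicates)]
    return _generate(config, theta, rng, ids, time_h=times)


def make_reference_correlation(config: SimConfig, n_samples: int) -> pd.DataFrame:
    """Spearman correlation matrix of the clock genes from an intact,
    low-noise simulation; serves as the baseline for the Mantel comparison.

    Requires an intact config (disruption = 0). Symmetric with unit
    diagonal; regenerable exactly from the config seed.
    """
    from scipy.stats import rankdata

    if config.disruption != 0:
        raise ConfigurationError("reference correlation requires an intact (disruption=0) config")
    if not config.clock_gene_map:
        raise ConfigurationError("config has no clock genes")
    config = dataclasses.replace(config, n_samples=n_samples)
    ds = simulate_population(config)
    genes = [g.symbol for g in config.clock_gene_map]
    sub = ds.matrix.values.loc[genes].to_numpy()
    ranks = np.apply_along_axis(rankdata, 1, sub)
    rho = np.atleast_2d(np.corrcoef(ranks))
    return pd.DataFrame(rho, index=genes, columns=genes)
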
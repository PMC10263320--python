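"""Cosinor rhythmometry, rhythmicity classification, transcriptome scans,
relative-phase tables, phase set enrichment (PSEA), and a harmonic
regression test for time-stamped designs.

The cosinor model is x = M + A*cos(theta - phi) fitted by closed-form least
squares on the design {1, cos(theta), sin(theta)} (period fixed at 24 h /
2*pi). M is the *fitmean* (mesor), A the amplitude, rAMP = A/M the relative
amplitude, phi the acrophase, and significance comes from the F-test of the
two harmonic terms against the intercept-only model.

A gene is called rhythmic when all four strict inequalities hold:
p < p_max, rAMP > ramp_min, rsq > rsq_min, fitmean > fitmean_min. Two
presets are packaged: ``human_default`` (p < 0.05, rAMP > 0.1, rsq > 0.1,
fitmean > 16) and ``mouse_reorder`` (same with p < 0.01).

PSEA asks whether the acrophases of a gene set cluster at a common
circadian time. The Kuiper statistic of the set's phases against the
uniform circular distribution is compared with a Monte-Carlo null drawn
from a background (uniform phases, or resampled from all rhythmic genes),
giving an exchangeable-valid permutation p-value; BH correction is applied
across sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from ._circular import TWO_PI, circ_diff, wrap
from .preprocess_io import ExpressionMatrix, GeneSetCollection

__all__ = [
    "CosinorFit",
    "RhythmicityCriteria",
    "PseaConfig",
    "HUMAN_DEFAULT",
    "MOUSE_REORDER",
    "cosinor_fit",
    "cosinor_fit_matrix",
    "classify_rhythmic",
    "rhythmic_scan",
    "phase_table_relative_to_anchor",
    "psea",
    "timecourse_rhythm_test",
]


@dataclass
class CosinorFit:
    gene: str
    fitmean: float
    amplitude: float
    ramp: float
    acrophase: float
    rsq: float
    p_value: float
    n: int
    rhythmic: Optional[bool] = None


@dataclass(frozen=True)
class RhythmicityCriteria:
    """All four thresholds are strict inequalities."""

    p_max: float
    ramp_min: float
    rsq_min: float
    fitmean_min: float

    def __post_init__(self):
        for name in ("p_max", "ramp_min", "rsq_min", "fitmean_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


HUMAN_DEFAULT = RhythmicityCriteria(p_max=0.05, ramp_min=0.1, rsq_min=0.1, fitmean_min=16.0)
MOUSE_REORDER = RhythmicityCriteria(p_max=0.01, ramp_min=0.1, rsq_min=0.1, fitmean_min=16.0)


@dataclass(frozen=True)
class PseaConfig:
    domain_h: float = 24.0
    min_item: int = 10
    n_sims: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if self.min_item < 2:
            raise ValueError("min_item must be >= 2")
        if not (0 < self.domain_h <= 24):
            raise ValueError("domain_h must lie in (0, 24]")


def _cosinor_core(Y: np.ndarray, theta: np.ndarray):
    """Vectorized closed-form cosinor over rows of Y (genes x samples).

    Returns fitmean, amplitude, acrophase, rsq, p arrays. Constant rows get
    amplitude 0, p 1, rsq 0 by contract.
    """
    n = theta.size
    X = np.column_stack([np.ones(n), np.cos(theta), np.sin(theta)])
    # least squares via the normal equations' pseudoinverse (3x3, well posed
    # unless the phases are pathologically degenerate)
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)   # 3 x genes
    fitted = (X @ beta).T
    resid = Y - fitted
    rss = np.sum(resid ** 2, axis=1)
    tss = np.sum((Y - Y.mean(axis=1, keepdims=True)) ** 2, axis=1)
    m = beta[0]
    amp = np.hypot(beta[1], beta[2])
    phi = wrap(np.arctan2(beta[2], beta[1]))
    with np.errstate(invalid="ignore", divide="ignore"):
        rsq = np.where(tss > 0, 1.0 - rss / tss, 0.0)
        fstat = ((tss - rss) / 2.0) / (rss / (n - 3))
    p = np.where(np.isfinite(fstat), stats.f.sf(fstat, 2, n - 3), 0.0)
    constant = tss <= 0
    amp = np.where(constant, 0.0, amp)
    p = np.where(constant, 1.0, p)
    rsq = np.clip(np.where(constant, 0.0, rsq), 0.0, 1.0)
    phi = np.where(constant, 0.0, phi)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return m, amp, phi, rsq, p


def cosinor_fit(expression, phases, gene: str = "gene") -> CosinorFit:
    """Least-squares cosinor fit of one gene's expression against phases.

    Raises below 4 samples (parameters + 1); warns below 8.
    """
    y = np.asarray(expression, dtype=float)
    theta = np.asarray(phases, dtype=float)
    if y.shape != theta.shape:
        raise ValueError("expression and phase vectors differ in length")
    if y.size < 4:
        raise ValueError("cosinor needs more samples than parameters (>= 4)")
    if y.size < 8:
        warnings.warn("cosinor fit on fewer than 8 samples is fragile")
    m, amp, phi, rsq, p = _cosinor_core(y[None, :], theta)
    fitmean = float(m[0])
    amplitude = float(amp[0])
    ramp = amplitude / fitmean if fitmean > 0 else np.nan
    return CosinorFit(gene, fitmean, amplitude, ramp, float(phi[0]),
                      float(rsq[0]), float(p[0]), y.size)


def cosinor_fit_matrix(matrix: ExpressionMatrix, phases) -> pd.DataFrame:
    """Cosinor fits for every gene at once; one row per gene with columns
    fitmean, amplitude, ramp, acrophase, acrophase_h, rsq, p."""
    phases = pd.Series(phases)
    theta = phases.reindex(matrix.samples).to_numpy(dtype=float)
    if np.isnan(theta).any():
        raise ValueError("phases missing for some samples")
    Y = matrix.values.to_numpy(dtype=float)
    m, amp, phi, rsq, p = _cosinor_core(Y, theta)
    with np.errstate(invalid="ignore", divide="ignore"):
        ramp = np.where(m > 0, amp / m, np.nan)
    return pd.DataFrame({
        "fitmean": m,
        "amplitude": amp,
        "ramp": ramp,
        "acrophase": phi,
        "acrophase_h": phi * 24.0 / TWO_PI,
        "rsq": rsq,
        "p": p,
    }, index=matrix.genes)


def classify_rhythmic(fit: CosinorFit, criteria: RhythmicityCriteria) -> bool:
    """True iff all four strict inequalities hold (values exactly at a
    threshold are NOT rhythmic)."""
    return bool(
        fit.p_value < criteria.p_max
        and fit.ramp > criteria.ramp_min
        and fit.rsq > criteria.rsq_min
        and fit.fitmean > criteria.fitmean_min
    )


@dataclass
class ScanResult:
    table: pd.DataFrame
    n_rhythmic: int
    n_genes: int

    @property
    def rhythmic_fraction(self) -> float:
        return self.n_rhythmic / self.n_genes if self.n_genes else 0.0


def rhythmic_scan(matrix: ExpressionMatrix, ordering,
                  criteria: RhythmicityCriteria = HUMAN_DEFAULT) -> ScanResult:
    """Transcriptome-wide cosinor scan on ordered samples.

    ``ordering`` is an OrderingResult or a phase Series covering all
    samples. Returns per-gene fits with rhythmic flags, sorted by p.
    """
    phases = getattr(ordering, "phases", ordering)
    table = cosinor_fit_matrix(matrix, phases)
    table["rhythmic"] = (
        (table["p"] < criteria.p_max)
        & (table["ramp"] > criteria.ramp_min)
        & (table["rsq"] > criteria.rsq_min)
        & (table["fitmean"] > criteria.fitmean_min)
    )
    table = table.sort_values("p", kind="stable")
    return ScanResult(table, int(table["rhythmic"].sum()), len(table))


def fits_from_table(table: pd.DataFrame) -> dict:
    """Convert a scan table into {gene: CosinorFit} (for phase alignment)."""
    out = {}
    for gene, row in table.iterrows():
        out[gene] = CosinorFit(
            gene=gene, fitmean=row["fitmean"], amplitude=row["amplitude"],
            ramp=row["ramp"], acrophase=row["acrophase"], rsq=row["rsq"],
            p_value=row["p"], n=0, rhythmic=bool(row.get("rhythmic", False)),
        )
    return out


def phase_table_relative_to_anchor(fits, anchor_gene: str = "ARNTL") -> pd.DataFrame:
    """Acrophases relative to an anchor gene.

    ``fits`` is a scan table (DataFrame with ``acrophase``/``rhythmic``) or
    {gene: CosinorFit}. Delta is the signed circular difference in (-pi, pi]
    and in hours (24 h cycle). The anchor must be present and rhythmic.
    """
    if isinstance(fits, pd.DataFrame):
        table = fits
    else:
        fits = {f.gene: f for f in fits} if not isinstance(fits, dict) else fits
        table = pd.DataFrame({
            "acrophase": {g: f.acrophase for g, f in fits.items()},
            "rhythmic": {g: bool(f.rhythmic) for g, f in fits.items()},
        })
    if anchor_gene not in table.index:
        raise ValueError(f"anchor gene {anchor_gene!r} missing from the fits")
    if "rhythmic" in table and not bool(table.loc[anchor_gene, "rhythmic"]):
        raise ValueError(f"anchor gene {anchor_gene!r} is not rhythmic")
    anchor_phi = float(table.loc[anchor_gene, "acrophase"])
    delta = circ_diff(table["acrophase"].to_numpy(dtype=float), anchor_phi)
    out = pd.DataFrame({
        "acrophase": table["acrophase"],
        "delta_phase": delta,
        "delta_hours": delta * 24.0 / TWO_PI,
    }, index=table.index)
    if "rhythmic" in table:
        out["rhythmic"] = table["rhythmic"]
    return out


# ----------------------------------------------------------------------
# phase set enrichment
# ----------------------------------------------------------------------

def _kuiper_stat(u_sorted: np.ndarray) -> np.ndarray:
    """Kuiper V against the uniform CDF for rows of sorted values in [0,1)."""
    n = u_sorted.shape[-1]
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - u_sorted, axis=-1)
    d_minus = np.max(u_sorted - (i - 1) / n, axis=-1)
    return d_plus + d_minus


def _kuiper(phases_h: np.ndarray, domain_h: float) -> float:
    u = np.sort(np.mod(phases_h, domain_h) / domain_h)
    return float(_kuiper_stat(u[None, :])[0])


def psea(rhythmic_phases: pd.Series, gene_sets: GeneSetCollection,
         config: PseaConfig = PseaConfig(),
         background: str = "uniform") -> pd.DataFrame:
    """Phase set enrichment: does each set's acrophase distribution cluster?

    ``rhythmic_phases`` maps gene -> acrophase in hours (only rhythmic genes
    should be supplied). For each set with >= min_item members among the
    rhythmic genes, the Kuiper statistic of the member phases against the
    uniform circular CDF is compared with n_sims Monte-Carlo draws of
    equally many phases from the background ("uniform", or
    "all_rhythmic" = resampling from the supplied phase pool).
    Columns: n, vector_strength, kuiper, p, q (BH), mean_phase_h.
    """
    if background not in ("uniform", "all_rhythmic"):
        raise ValueError("background must be 'uniform' or 'all_rhythmic'")
    phases = pd.Series(rhythmic_phases, dtype=float)
    pool = phases.to_numpy()
    rng = np.random.default_rng(config.seed)
    rows = []
    for gs in gene_sets:
        members = [g for g in gs.members if g in phases.index]
        if len(members) < config.min_item:
            continue
        ph = phases.loc[members].to_numpy()
        m = len(ph)
        k_obs = _kuiper(ph, config.domain_h)
        if background == "uniform":
            sims = rng.uniform(0.0, config.domain_h, size=(config.n_sims, m))
        else:
            sims = rng.choice(pool, size=(config.n_sims, m), replace=True)
        u = np.sort(np.mod(sims, config.domain_h) / config.domain_h, axis=1)
        k_null = _kuiper_stat(u)
        p = (int(np.sum(k_null >= k_obs)) + 1) / (config.n_sims + 1)
        ang = TWO_PI * ph / config.domain_h
        vec = complex(np.mean(np.cos(ang)), np.mean(np.sin(ang)))
        mean_phase_h = wrap(np.angle(vec)) * config.domain_h / TWO_PI
        rows.append({
            "set": gs.name, "n": m,
            "vector_strength": abs(vec),
            "kuiper": k_obs, "p": p,
            "mean_phase_h": float(mean_phase_h),
        })
    if not rows:
        warnings.warn("no gene set passed the min_item threshold")
        return pd.DataFrame(columns=["set", "n", "vector_strength", "kuiper",
                                     "p", "q", "mean_phase_h"]).set_index("set")
    out = pd.DataFrame(rows).set_index("set")
    out["q"] = stats.false_discovery_control(out["p"].to_numpy(), method="bh")
    return out.sort_values("p", kind="stable")


def timecourse_rhythm_test(matrix: ExpressionMatrix, q_max: float = 0.05,
                           ramp_min: float = 0.1) -> pd.DataFrame:
    """Harmonic-regression rhythmicity test for time-stamped designs.

    Uses collection times from metadata column ``time_h`` folded to a fixed
    24 h period (theta = 2*pi*(t mod 24)/24), cosinor per gene, BH-FDR
    across genes. A gene is rhythmic iff q < 0.05 and rAMP > 0.1 (both
    strict). Columns: p, q, ramp, acrophase_h, period_h, rhythmic.
    """
    if "time_h" not in matrix.metadata:
        raise ValueError("matrix metadata lacks the 'time_h' column")
    t = matrix.metadata["time_h"].to_numpy(dtype=float)
    if np.isnan(t).any():
        raise ValueError("time_h missing for some samples")
    if np.unique(np.mod(t, 24.0)).size < 2:
        raise ValueError("need >= 2 distinct timepoints")
    theta = TWO_PI * np.mod(t, 24.0) / 24.0
    fits = cosinor_fit_matrix(matrix, pd.Series(theta, index=matrix.samples))
    q = stats.false_discovery_control(fits["p"].to_numpy(), method="bh")
    out = pd.DataFrame({
        "p": fits["p"],
        "q": q,
        "ramp": fits["ramp"],
        "acrophase_h": fits["acrophase_h"],
        "period_h": 24.0,
    }, index=fits.index)
    out["rhythmic"] = (out["q"] < q_max) & (out["ramp"] > ramp_min)
    return out.sort_values("p", kind="stable")
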
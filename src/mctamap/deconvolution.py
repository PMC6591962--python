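"""Constrained mixture deconvolution of plasma cfDNA tissue fractions.

The plasma MePM of a tissue-aggregated marker is modelled as a linear
mixture of the reference tissues,

    MP_i = sum_k MT_ik * P_k ,

where MT_ik is marker aggregate i's mean MePM in tissue k and P_k the
proportional contribution of tissue k to plasma cfDNA.  White blood cells
are omitted as a component because the markers were selected to be silent
in WBC, leaving one aggregated equation per non-hematopoietic tissue (8 by
default).  The system is solved by particle swarm optimization under box
constraints 0 <= P_k <= 1, taking the element-wise median of ten
independent runs as the readout.  Residual WBC cross-reactivity is then
removed by subtracting per-tissue background means measured in paired WBC
samples and zeroing fractions below the mean + 3 SD background threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .markers import MarkerSet, aggregate_markers, panel_max_marker

DEFAULT_TISSUES = (
    "liver", "lung", "stomach", "colon", "kidney", "pancreas", "muscle", "skin",
)

#: mean non-specific background fraction measured in paired WBC samples
WBC_BACKGROUND_MEANS = (0.00015, 0.0, 0.0036, 0.0, 0.0, 0.0, 0.00066, 0.0)
#: mean + 3 SD zeroing thresholds from the same WBC samples
WBC_BACKGROUND_THRESHOLDS = (0.0011, 0.0, 0.020, 0.00082, 0.00036, 0.00023, 0.0057, 0.0)


@dataclass(frozen=True)
class PSOConfig:
    """Particle swarm settings.

    Canonical constriction coefficients (inertia 0.729, cognitive = social
    = 1.49445) with particles clamped to the [0, 1] box and their velocity
    zeroed at the boundary.  ``n_runs`` independent restarts are taken and
    summarised by their element-wise median.
    """

    swarm_size: int = 50
    iterations: int = 500
    inertia: float = 0.729
    cognitive: float = 1.49445
    social: float = 1.49445
    lower: float = 0.0
    upper: float = 1.0
    #: iterations without global-best improvement before the swarm's
    #: velocities are re-randomized (personal/global bests kept); guards
    #: against premature collapse onto the box boundary
    stall_restart: int = 25
    n_runs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.upper <= self.lower:
            raise ValueError("upper bound must exceed lower bound")


@dataclass(frozen=True)
class WBCBackgroundModel:
    """Per-tissue WBC background means and mean+3SD zeroing thresholds (fractions)."""

    tissues: tuple[str, ...] = DEFAULT_TISSUES
    means: tuple[float, ...] = WBC_BACKGROUND_MEANS
    thresholds: tuple[float, ...] = WBC_BACKGROUND_THRESHOLDS

    def __post_init__(self) -> None:
        if not (len(self.tissues) == len(self.means) == len(self.thresholds)):
            raise ValueError("tissues, means and thresholds must have equal length")
        for t, m, th in zip(self.tissues, self.means, self.thresholds):
            if not 0 <= m <= th:
                raise ValueError(f"{t}: need 0 <= mean ({m}) <= threshold ({th})")

    @classmethod
    def from_wbc_fractions(cls, fractions: pd.DataFrame, n_sd: float = 3.0) -> "WBCBackgroundModel":
        """Calibrate from deconvolved WBC-only samples (rows = samples,
        columns = tissues): mean and mean + n_sd * SD per tissue."""
        mu = fractions.mean(axis=0)
        sd = fractions.std(axis=0, ddof=1).fillna(0.0)
        return cls(
            tissues=tuple(fractions.columns),
            means=tuple(float(v) for v in mu),
            thresholds=tuple(float(v) for v in (mu + n_sd * sd)),
        )

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean": self.means, "threshold": self.thresholds}, index=list(self.tissues)
        )


@dataclass
class DeconvolutionResult:
    raw_fractions: pd.Series
    corrected_fractions: pd.Series | None
    per_run: pd.DataFrame  # runs x tissues
    residual: float
    ge_per_ml: pd.Series | None = None


def build_system(
    marker_set: MarkerSet,
    panel: pd.DataFrame,
    plasma: pd.Series,
    tissues: Sequence[str] = DEFAULT_TISSUES,
) -> tuple[pd.DataFrame, pd.Series]:
    """Aggregate markers per tissue into the linear system (MT, MP).

    Row i of MT is tissue i's marker aggregate evaluated in every reference
    tissue column k; MP_i is the same aggregate evaluated on the plasma
    MePM vector.  The aggregate sums a tissue's markers minus its
    panel-defined largest.  Tissues with no retained markers are dropped
    from the system with a warning.
    """
    rows = []
    mp = []
    kept = []
    for t in tissues:
        mk = marker_set.by_tissue.get(t, [])
        if not mk:
            warnings.warn(f"tissue {t!r} has no retained markers; equation dropped")
            continue
        excl = panel_max_marker(panel, mk, t)
        row = {
            k: aggregate_markers(panel.loc[mk, k], exclude=excl) for k in tissues
        }
        rows.append(row)
        mp.append(aggregate_markers(plasma.loc[mk], exclude=excl))
        kept.append(t)
    mt = pd.DataFrame(rows, index=kept, columns=list(tissues))
    return mt, pd.Series(mp, index=kept, name="MP")


def _pso_single(
    mt: np.ndarray, mp: np.ndarray, config: PSOConfig, rng: np.random.Generator
) -> np.ndarray:
    n_dim = mt.shape[1]
    lo, hi = config.lower, config.upper
    span = hi - lo
    x = rng.uniform(lo, hi, size=(config.swarm_size, n_dim))
    v = rng.uniform(-span, span, size=(config.swarm_size, n_dim)) * 0.1

    def objective(pos: np.ndarray) -> np.ndarray:
        resid = mp[None, :] - pos @ mt.T
        return np.einsum("ij,ij->i", resid, resid)

    pbest = x.copy()
    pbest_f = objective(x)
    g = int(np.argmin(pbest_f))
    gbest, gbest_f = pbest[g].copy(), pbest_f[g]

    stalled = 0
    for _ in range(config.iterations):
        r1 = rng.uniform(size=x.shape)
        r2 = rng.uniform(size=x.shape)
        v = (
            config.inertia * v
            + config.cognitive * r1 * (pbest - x)
            + config.social * r2 * (gbest[None, :] - x)
        )
        x = x + v
        below, above = x < lo, x > hi
        x = np.clip(x, lo, hi)
        v[below | above] = 0.0  # absorb at the box boundary
        f = objective(x)
        improved = f < pbest_f
        pbest[improved] = x[improved]
        pbest_f[improved] = f[improved]
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f * (1.0 - 1e-12):
            gbest, gbest_f = pbest[g].copy(), pbest_f[g]
            stalled = 0
        else:
            stalled += 1
        if config.stall_restart and stalled >= config.stall_restart:
            # swarm collapsed without improving: shake the velocities,
            # keeping the personal/global best memory
            v = rng.uniform(-span, span, size=v.shape) * 0.1
            stalled = 0
    return gbest


def pso_solve(
    mt: pd.DataFrame | np.ndarray,
    mp: pd.Series | np.ndarray,
    config: PSOConfig | None = None,
) -> tuple[pd.Series | np.ndarray, pd.DataFrame | np.ndarray, float]:
    """Solve MP = MT @ P for P in [0,1]^K by particle swarm optimization.

    Minimises the sum of squared residuals.  Runs ``config.n_runs``
    independently seeded swarms and returns (median solution, per-run
    solutions, residual of the median solution).
    """
    config = config or PSOConfig()
    mt_arr = np.asarray(mt, dtype=float)
    mp_arr = np.asarray(mp, dtype=float)
    if not (np.all(np.isfinite(mt_arr)) and np.all(np.isfinite(mp_arr))):
        raise ValueError("MT and MP must be finite")
    ss = np.random.SeedSequence(config.seed)
    runs = np.vstack(
        [
            _pso_single(mt_arr, mp_arr, config, np.random.default_rng(child))
            for child in ss.spawn(config.n_runs)
        ]
    )
    median = np.median(runs, axis=0)
    resid = mp_arr - mt_arr @ median
    residual = float(resid @ resid)
    if isinstance(mt, pd.DataFrame):
        tissues = list(mt.columns)
        return (
            pd.Series(median, index=tissues, name="fraction"),
            pd.DataFrame(runs, columns=tissues),
            residual,
        )
    return median, runs, residual


def correct_background(
    raw: pd.Series, model: WBCBackgroundModel | None = None
) -> pd.Series:
    """Subtract WBC background and zero sub-threshold fractions.

    The mean+3SD threshold is applied to the *measured* (raw) fractions;
    survivors then have the mean background subtracted (floored at 0).
    """
    model = model or WBCBackgroundModel()
    means = pd.Series(model.means, index=list(model.tissues))
    thresholds = pd.Series(model.thresholds, index=list(model.tissues))
    raw = raw.astype(float)
    out = pd.Series(0.0, index=raw.index, name="corrected_fraction")
    for t in raw.index:
        if t not in means.index:
            raise KeyError(f"background model lacks tissue {t!r}")
        if raw[t] >= thresholds[t] and raw[t] > 0:
            out[t] = max(0.0, raw[t] - means[t])
    return out


def absolute_ge(
    fractions: pd.Series,
    cfdna_ng_per_ml: float,
    pg_per_haploid_ge: float = 3.3,
) -> pd.Series:
    """Convert tissue fractions to absolute haploid genome equivalents per mL.

    GE/mL = fraction * cfDNA (ng/mL) * 1000 / pg-per-haploid-genome
    (3.3 pg by default).
    """
    if pg_per_haploid_ge <= 0:
        raise ValueError("pg_per_haploid_ge must be positive")
    if cfdna_ng_per_ml < 0:
        raise ValueError("cfDNA concentration must be non-negative")
    return fractions.astype(float) * (cfdna_ng_per_ml * 1000.0 / pg_per_haploid_ge)


def deconvolve(
    marker_set: MarkerSet,
    panel: pd.DataFrame,
    plasma: pd.Series,
    tissues: Sequence[str] = DEFAULT_TISSUES,
    pso: PSOConfig | None = None,
    background: WBCBackgroundModel | None = None,
    cfdna_ng_per_ml: float | None = None,
) -> DeconvolutionResult:
    """End-to-end single-sample deconvolution: build, solve, correct, convert.

    ``background=None`` skips correction (raw fractions only); pass
    ``WBCBackgroundModel()`` for the default WBC constants.
    """
    mt, mp = build_system(marker_set, panel, plasma, tissues=tissues)
    raw, per_run, residual = pso_solve(mt, mp, pso)
    raw = raw.reindex(list(tissues), fill_value=0.0)
    corrected = correct_background(raw, background) if background is not None else None
    ge = None
    if cfdna_ng_per_ml is not None:
        ge = absolute_ge(corrected if corrected is not None else raw, cfdna_ng_per_ml)
    return DeconvolutionResult(
        raw_fractions=raw,
        corrected_fractions=corrected,
        per_run=per_run,
        residual=residual,
        ge_per_ml=ge,
    )


def evaluate_recovery(
    truth: Sequence[float], estimates: Sequence[float]
) -> tuple[float, float, float]:
    """OLS fit of estimated vs true spike-in fraction: (slope, intercept, R^2)."""
    t = np.asarray(truth, dtype=float)
    e = np.asarray(estimates, dtype=float)
    if len(np.unique(t)) < 3:
        raise ValueError("need >= 3 distinct true fractions for a recovery fit")
    fit = stats.linregress(t, e)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def estimate_detection_limit(
    series: Mapping[float, Sequence[float]],
    null_estimates: Sequence[float],
    alpha: float = 0.05,
) -> tuple[float | None, pd.DataFrame]:
    """Smallest spiked fraction distinguishable from WBC-only background.

    Per spike level, a two-tailed Student t test compares the estimated
    fractions against the WBC-only (null) estimates; the detection limit is
    the smallest grid fraction with P < alpha, or None when no level
    separates.  Returns (limit, per-level table of means and p-values).
    Degenerate case: when both groups are constant, p = 1 if their values
    coincide and 0 otherwise.
    """
    null = np.asarray(null_estimates, dtype=float)
    if null.size < 2:
        raise ValueError("need >= 2 WBC-only replicates")
    rows = []
    limit = None
    for frac in sorted(series):
        est = np.asarray(series[frac], dtype=float)
        if est.size < 2:
            raise ValueError(f"need >= 2 replicates at fraction {frac}")
        if np.ptp(est) == 0 and np.ptp(null) == 0:
            p = 1.0 if est[0] == null[0] else 0.0
        else:
            p = float(stats.ttest_ind(est, null, equal_var=True).pvalue)
        rows.append(dict(fraction=frac, mean_estimate=float(est.mean()),
                         sd_estimate=float(est.std(ddof=1)), p_value=p,
                         detected=p < alpha))
        if limit is None and p < alpha:
            limit = float(frac)
    return limit, pd.DataFrame.from_records(rows)
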
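"""Replicated benchmark of the pi0 estimators over the (pi0, rho) space.

Each grid point (pi0, rho[, n]) gets R replicate in-silico experiments:
simulate a study, compute per-gene p-values, run all five estimators on the
same p-value vector.  Accuracy is summarised by the mean absolute error
(MAE) over replicates, with RMSE as a secondary measure.  Because every
method sees identical simulated data within a replicate, methods are
compared by paired t-tests on per-replicate absolute errors, and each point
is classified relative to a reference method (ZG04 by default):

blue    — the reference is significantly more accurate than every other
          method (all four paired p-values below the threshold);
red     — some other method is significantly more accurate than the
          reference;
yellow  — neither: at least one method ties the reference.

The significance threshold is deliberately stringent (default 1e-5) so that
across a whole grid of points, each contributing four tests, fewer than one
significant call is expected to be false.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import METHODS, estimate_all
from .synthetic import SimulationConfig, compute_pvalues, simulate_study

__all__ = [
    "ReplicateBatch",
    "ErrorSummary",
    "RegionMap",
    "run_replicates",
    "error_summary",
    "compare_methods_paired",
    "classify_grid_point",
    "sweep_parameter_space",
]

logger = logging.getLogger("pi0bench")

#: reference method for region classification
REFERENCE = "ZG04"
#: default paired-test significance threshold; with ~190 grid points x 4
#: tests this keeps the expected number of false significance claims < 1
DEFAULT_THRESHOLD = 1e-5


@dataclass
class ReplicateBatch:
    """Estimates from R replicate experiments at one parameter point."""

    config: SimulationConfig
    R: int
    estimates: pd.DataFrame     # R x len(methods), one column per method
    truth: float                # the generating pi0
    seeds: np.ndarray
    failures: dict[str, int] = field(default_factory=dict)

    @property
    def abs_errors(self) -> pd.DataFrame:
        return (self.estimates - self.truth).abs()


@dataclass(frozen=True)
class ErrorSummary:
    method: str
    mae: float
    mae_se: float
    rmse: float


@dataclass
class RegionMap:
    """Tidy per-(point, method) results plus per-point labels."""

    table: pd.DataFrame         # pi0, rho, n1, n2, method, mae, mae_se, rmse, p_vs_reference, reference_better, label
    reference: str
    threshold: float
    master_seed: int
    R: int


def _derive_seed(master_seed: int, *coords: float) -> np.random.SeedSequence:
    # entropy mixes the master seed with the (scaled, exact for grid values)
    # point coordinates, so the stream per point is evaluation-order invariant
    ints = [int(master_seed)] + [int(round(c * 1_000_000)) for c in coords]
    return np.random.SeedSequence(ints)


def run_replicates(config: SimulationConfig, R: int, master_seed: int,
                   methods: tuple[str, ...] = METHODS) -> ReplicateBatch:
    """Simulate R independent replicates at *config* and estimate pi0 each time.

    Per-replicate seeds are spawned deterministically from the master seed;
    the same master seed reproduces the batch bit-for-bit.  An estimator
    failure on a replicate is recorded as NaN (and counted) rather than
    aborting the batch.
    """
    if R < 2:
        raise ValueError("need at least 2 replicates")
    ss = _derive_seed(master_seed, config.pi0, config.rho, config.n1, config.n2)
    seeds = np.array([int(child.generate_state(1, dtype=np.uint32)[0] >> 1)
                      for child in ss.spawn(R)])
    rows = np.full((R, len(methods)), np.nan)
    failures = {m: 0 for m in methods}
    for j, seed in enumerate(seeds):
        cfg = replace(config, seed=int(seed))
        pvals = compute_pvalues(simulate_study(cfg))
        for col, m in enumerate(methods):
            try:
                rows[j, col] = estimate_all(pvals, methods=(m,))[m].pi0_hat
            except Exception as exc:  # noqa: BLE001 - recorded, not fatal
                failures[m] += 1
                logger.warning("replicate %d: %s failed: %s", j, m, exc)
    estimates = pd.DataFrame(rows, columns=list(methods))
    return ReplicateBatch(config=config, R=R, estimates=estimates,
                          truth=config.pi0, seeds=seeds,
                          failures={m: c for m, c in failures.items() if c})


def error_summary(batch: ReplicateBatch) -> dict[str, ErrorSummary]:
    """MAE, its standard error, and RMSE per method over the batch.

    MAE = mean |pi0_hat - pi0| over replicates; RMSE = sqrt(mean squared
    error); mae_se = sample SD of the absolute errors / sqrt(R).  NaN
    estimates (failed replicates) are excluded per method.
    """
    out = {}
    for m in batch.estimates.columns:
        err = batch.abs_errors[m].dropna().to_numpy()
        out[m] = ErrorSummary(
            method=m,
            mae=float(err.mean()),
            mae_se=float(err.std(ddof=1) / np.sqrt(err.size)),
            rmse=float(np.sqrt((err ** 2).mean())),
        )
    return out


def compare_methods_paired(errors_a: np.ndarray,
                           errors_b: np.ndarray) -> tuple[float, str]:
    """Paired t-test on per-replicate absolute errors of two methods.

    The pairing is by replicate: both methods were run on the same simulated
    data, so the difference removes between-replicate variation.  Returns
    the two-sided p-value and which method had the lower mean absolute
    error ('a', 'b', or 'tie').  Degenerate cases: all differences exactly
    zero -> (1.0, 'tie'); zero variance with nonzero mean -> p = 0.
    """
    a = np.asarray(errors_a, float)
    b = np.asarray(errors_b, float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length error vectors of length >= 2")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 2:
        return float("nan"), "tie"
    diff = a - b
    direction = "a" if diff.mean() < 0 else ("b" if diff.mean() > 0 else "tie")
    if np.all(diff == 0.0):
        return 1.0, "tie"
    if diff.std(ddof=1) == 0.0:
        return 0.0, direction
    p = float(stats.ttest_rel(a, b).pvalue)
    return p, direction


def classify_grid_point(batch: ReplicateBatch, reference: str = REFERENCE,
                        threshold: float = DEFAULT_THRESHOLD
                        ) -> tuple[str, pd.DataFrame]:
    """Blue/yellow/red label for one parameter point.

    blue: the reference beats every other method with paired p < threshold;
    red: some method beats the reference with p < threshold;
    yellow: otherwise.  Returns the label and the per-method comparison
    table (mae, mae_se, rmse, p_vs_reference, reference_better).
    """
    if reference not in batch.estimates.columns:
        raise ValueError(f"reference {reference!r} missing from batch")
    summaries = error_summary(batch)
    ref_err = batch.abs_errors[reference].to_numpy()
    rows = []
    ref_sig_better, other_sig_better = [], []
    for m in batch.estimates.columns:
        if m == reference:
            p, ref_better = np.nan, None
        else:
            p, direction = compare_methods_paired(ref_err,
                                                  batch.abs_errors[m].to_numpy())
            ref_better = direction == "a"
            if np.isfinite(p) and p < threshold:
                (ref_sig_better if ref_better else other_sig_better).append(m)
        s = summaries[m]
        rows.append({"method": m, "mae": s.mae, "mae_se": s.mae_se,
                     "rmse": s.rmse, "p_vs_reference": p,
                     "reference_better": ref_better})
    n_other = len(batch.estimates.columns) - 1
    if other_sig_better:
        label = "red"
    elif len(ref_sig_better) == n_other:
        label = "blue"
    else:
        label = "yellow"
    return label, pd.DataFrame(rows)


def sweep_parameter_space(pi0_grid, rho_grid, base_config: SimulationConfig,
                          R: int = 100, threshold: float = DEFAULT_THRESHOLD,
                          master_seed: int = 0, n_grid=None,
                          reference: str = REFERENCE) -> RegionMap:
    """Classify every (pi0, rho[, n]) grid point of the parameter space.

    Runs ``run_replicates`` + ``classify_grid_point`` at each point.  When
    ``n_grid`` is given, the sweep additionally varies the balanced sample
    size n1 = n2 = n at every (pi0, rho) point (the sample-size excursions);
    otherwise the base config's sample sizes are used.  Per-point seeds are
    derived from the coordinates and the master seed, so the output is
    independent of evaluation order.  A point where any method failed on
    more than 10% of replicates is labelled 'flagged' instead.
    """
    pi0_grid = list(pi0_grid)
    rho_grid = list(rho_grid)
    if not pi0_grid or not rho_grid:
        raise ValueError("grids must be non-empty")
    n_pairs = ([(base_config.n1, base_config.n2)] if n_grid is None
               else [(int(n), int(n)) for n in n_grid])
    frames = []
    for pi0 in pi0_grid:
        for rho in rho_grid:
            for n1, n2 in n_pairs:
                cfg = replace(base_config, pi0=float(pi0), rho=float(rho),
                              n1=n1, n2=n2)
                try:
                    batch = run_replicates(cfg, R, master_seed)
                    label, table = classify_grid_point(batch, reference,
                                                       threshold)
                    if any(c > 0.1 * R for c in batch.failures.values()):
                        label = "flagged"
                except Exception as exc:  # noqa: BLE001 - keep sweeping
                    logger.warning("point (%.3g, %.3g, n=%d) failed: %s",
                                   pi0, rho, n1, exc)
                    label, table = "missing", pd.DataFrame(
                        {"method": list(METHODS)})
                table = table.assign(pi0=pi0, rho=rho, n1=n1, n2=n2,
                                     label=label)
                frames.append(table)
                logger.info("point (pi0=%.3g, rho=%.3g, n=%d): %s",
                            pi0, rho, n1, label)
    cols = ["pi0", "rho", "n1", "n2", "method", "mae", "mae_se", "rmse",
            "p_vs_reference", "reference_better", "label"]
    table = pd.concat(frames, ignore_index=True)
    table = table[[c for c in cols if c in table.columns]]
    return RegionMap(table=table, reference=reference, threshold=threshold,
                     master_seed=master_seed, R=R)
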
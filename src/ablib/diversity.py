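"""Hill-number diversity, species-accumulation curves, and asymptotic
richness estimation by negative-exponential fitting.

The Hill number of order q is ``qD = (sum_i p_i^q)^(1/(1-q))`` with the
entropy limit ``exp(-sum p_i ln p_i)`` at q = 1; q = 0 is clonotype richness,
q = 2 the inverse Simpson index.  Accumulation curves subsample reads without
replacement (rarefaction), clonotype each subsample at the requested
criterion, and the asymptote of ``S(n) = S_max (1 - exp(-n / tau))`` fitted to
the averaged curve estimates total richness.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .clonotype import ClonotypeTable, hierarchical_clonotype


def hill_diversity(counts: Mapping[str, int] | Sequence[float] | ClonotypeTable,
                   q: float) -> float:
    """Diversity of order q of a clone-count table."""
    if isinstance(counts, ClonotypeTable):
        values = [c.count for c in counts.clonotypes]
    elif isinstance(counts, Mapping):
        values = list(counts.values())
    else:
        values = list(counts)
    if not values:
        raise ValueError("empty count table")
    if q < 0:
        raise ValueError("q must be non-negative")
    p = np.asarray(values, dtype=float)
    p = p / p.sum()
    if abs(q - 1.0) < 1e-12:
        return float(np.exp(-np.sum(p * np.log(p, where=p > 0, out=np.zeros_like(p)))))
    return float(np.sum(p ** q) ** (1.0 / (1.0 - q)))


def diversity_spectrum(counts, qs: Sequence[float] = (0.0, 1.0, 2.0)) -> dict[float, float]:
    return {float(q): hill_diversity(counts, q) for q in qs}


def accumulation_curve(
    read_keys: Sequence[str],
    grid: Sequence[int],
    criterion: str | int = 0,
    scheme: str = "cdr3",
    n_reps: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Clonotype richness vs reads sampled.

    ``read_keys`` is the per-read clonotype key stream (one entry per read).
    Returns a tidy frame (n, rep, s_obs); average over reps for fitting.
    """
    total = len(read_keys)
    grid = sorted(set(int(n) for n in grid))
    if any(n < 1 for n in grid):
        raise ValueError("grid values must be >= 1")
    if grid and grid[-1] > total:
        raise ValueError(f"grid point {grid[-1]} exceeds total reads {total}")
    rng = np.random.default_rng(seed)
    keys = np.asarray(read_keys, dtype=object)
    rows = []
    for rep in range(n_reps):
        perm = rng.permutation(total)
        for n in grid:
            sample = keys[perm[:n]]
            table = Counter(sample.tolist())
            s_obs = len(hierarchical_clonotype(table, criterion, scheme))
            rows.append({"n": n, "rep": rep, "s_obs": s_obs})
    return pd.DataFrame(rows)


def average_curve(curve: pd.DataFrame) -> pd.DataFrame:
    return curve.groupby("n", as_index=False)["s_obs"].mean()


@dataclass
class AccumulationFit:
    s_max: float
    tau: float
    rss: float
    converged: bool
    message: str
    curve: pd.DataFrame

    @property
    def rate(self) -> float:
        return 1.0 / self.tau if self.tau > 0 else float("inf")


def fit_negative_exponential(curve: pd.DataFrame) -> AccumulationFit:
    """Least-squares fit of S(n) = S_max (1 - exp(-n/tau)) to an averaged curve.

    Initialization: S_max <- 1.1 x max observed, tau <- n at half max.
    Non-convergence is reported in the result, not raised.
    """
    if {"rep"} <= set(curve.columns):
        curve = average_curve(curve)
    n = curve["n"].to_numpy(dtype=float)
    s = curve["s_obs"].to_numpy(dtype=float)
    if len(np.unique(n)) < 3:
        raise ValueError("need at least 3 distinct n points")

    s_max0 = 1.1 * s.max()
    half = 0.5 * s.max()
    tau0 = float(n[int(np.argmax(s >= half))])  # n at half-maximum

    def resid(theta):
        s_max, tau = theta
        return s_max * (1.0 - np.exp(-n / tau)) - s

    try:
        fit = least_squares(
            resid, x0=[s_max0, max(tau0, 1.0)],
            bounds=([s.max(), 1e-9], [np.inf, np.inf]),
            xtol=1e-8, ftol=1e-12, gtol=1e-12, max_nfev=500,
        )
        s_max, tau = fit.x
        return AccumulationFit(
            s_max=float(s_max), tau=float(tau), rss=float(np.sum(fit.fun ** 2)),
            converged=bool(fit.success), message=fit.message, curve=curve,
        )
    except Exception as exc:  # pragma: no cover - defensive
        return AccumulationFit(
            s_max=float("nan"), tau=float("nan"), rss=float("nan"),
            converged=False, message=str(exc), curve=curve,
        )


def diversity_report(
    read_keys: Sequence[str],
    criteria: Sequence[str | int] = (0, 1, 2, 3, "abundance_only"),
    scheme: str = "cdr3",
    grid: Sequence[int] | None = None,
    n_reps: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-criterion measured richness, Hill numbers and fitted asymptote."""
    total = len(read_keys)
    if grid is None:
        grid = np.unique(np.geomspace(max(10, total // 100), total, 8).astype(int))
    table = Counter(read_keys)
    rows = []
    for criterion in criteria:
        ct = hierarchical_clonotype(table, criterion, scheme)
        curve = accumulation_curve(read_keys, grid, criterion, scheme, n_reps, seed)
        fit = fit_negative_exponential(curve)
        rows.append({
            "criterion": ct.criterion,
            "reads": total,
            "richness": len(ct),
            "hill_q1": hill_diversity(ct, 1.0),
            "hill_q2": hill_diversity(ct, 2.0),
            "estimated_richness": fit.s_max,
            "fit_converged": fit.converged,
        })
    return pd.DataFrame(rows)
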
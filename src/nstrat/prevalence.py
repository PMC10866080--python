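"""Bootstrap prevalence estimation for the strategy matrix.

Each replicate resamples genomes with replacement (plain scheme) or draws a
capped number of genomes per taxon (taxon-balanced scheme) and records the
per-strategy count; summaries are the replicate median and 2.5/97.5
percentiles computed with linear interpolation between order statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PrevalenceEstimate:
    strategy: str
    point_count: int
    boot_median: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    scheme: str
    n_genomes: int
    proportion: float

    def __post_init__(self) -> None:
        if not self.ci_low <= self.boot_median <= self.ci_high:
            raise ValueError("percentile summaries out of order")


def _replicate_counts_plain(
    X: np.ndarray, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    n = X.shape[0]
    counts = np.empty((n_boot, X.shape[1]), dtype=np.int64)
    # Chunked so n_boot = 1e5 at small n stays in memory.
    chunk = max(1, int(5e7 // max(n, 1)))
    for start in range(0, n_boot, chunk):
        b = min(chunk, n_boot - start)
        idx = rng.integers(0, n, size=(b, n))
        counts[start:start + b] = X[idx].sum(axis=1)
    return counts


def _replicate_counts_balanced(
    X: np.ndarray,
    taxa: np.ndarray,
    n_boot: int,
    rng: np.random.Generator,
    k: int | None,
) -> np.ndarray:
    groups = []
    for taxon in pd.unique(taxa):
        members = np.flatnonzero(taxa == taxon)
        if members.size == 0:
            warnings.warn(f"empty taxon {taxon!r} skipped")
            continue
        groups.append(members)
    if k is None:
        k = int(np.median([g.size for g in groups]))
        k = max(k, 1)
    counts = np.zeros((n_boot, X.shape[1]), dtype=np.int64)
    for members in groups:
        take = min(k, members.size)
        idx = members[rng.integers(0, members.size, size=(n_boot, take))]
        counts += X[idx].sum(axis=1)
    return counts


def bootstrap_prevalence(
    matrix: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    scheme: str = "plain",
    taxonomy: pd.Series | None = None,
    k: int | None = None,
) -> list[PrevalenceEstimate]:
    """Bootstrap per-strategy genome counts.

    ``matrix`` is a genome x strategy boolean DataFrame.  The balanced
    scheme requires ``taxonomy`` (a per-genome taxon label aligned with the
    matrix index) and draws ``min(k, available)`` genomes per taxon each
    replicate (default k: the median per-taxon size).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if matrix.empty:
        raise ValueError("empty strategy matrix")
    if scheme not in {"plain", "taxon_balanced"}:
        raise ValueError(f"unknown scheme {scheme!r}")
    X = matrix.to_numpy(dtype=np.int64)
    rng = np.random.default_rng(seed)
    if scheme == "plain":
        counts = _replicate_counts_plain(X, n_boot, rng)
    else:
        if taxonomy is None:
            raise ValueError("taxonomy required for taxon_balanced scheme")
        taxa = taxonomy.loc[matrix.index].to_numpy()
        counts = _replicate_counts_balanced(X, taxa, n_boot, rng, k)

    n = X.shape[0]
    point = X.sum(axis=0)
    estimates = []
    for j, strategy in enumerate(matrix.columns):
        col = counts[:, j]
        lo, med, hi = np.percentile(col, [2.5, 50.0, 97.5], method="linear")
        estimates.append(PrevalenceEstimate(
            strategy=str(strategy),
            point_count=int(point[j]),
            boot_median=float(med),
            ci_low=float(lo),
            ci_high=float(hi),
            n_boot=n_boot,
            seed=seed,
            scheme=scheme,
            n_genomes=n,
            proportion=float(point[j] / n),
        ))
    return estimates


def rank_strategies(estimates: list[PrevalenceEstimate]) -> list[dict]:
    """Sort strategies by bootstrapped median (desc), ties broken by point
    count (desc) then name; annotate whether adjacent CIs overlap."""
    seen = [e.strategy for e in estimates]
    if len(set(seen)) != len(seen):
        raise ValueError("duplicate strategies in estimate list")
    ordered = sorted(estimates, key=lambda e: (-e.boot_median, -e.point_count, e.strategy))
    out = []
    for i, e in enumerate(ordered):
        overlap = None
        if i + 1 < len(ordered):
            nxt = ordered[i + 1]
            overlap = bool(e.ci_low <= nxt.ci_high and nxt.ci_low <= e.ci_high)
        out.append({
            "strategy": e.strategy,
            "boot_median": e.boot_median,
            "point_count": e.point_count,
            "ci_overlaps_next": overlap,
        })
    return out


def estimates_to_frame(estimates: list[PrevalenceEstimate]) -> pd.DataFrame:
    return pd.DataFrame([{
        "strategy": e.strategy,
        "point_count": e.point_count,
        "proportion": round(e.proportion, 6),
        "boot_median": e.boot_median,
        "ci_low": e.ci_low,
        "ci_high": e.ci_high,
        "n_boot": e.n_boot,
        "scheme": e.scheme,
        "seed": e.seed,
    } for e in estimates])
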
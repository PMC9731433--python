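"""Site-frequency-spectrum construction and SFS-matched control sampling.

Control (non-archaic) variants are sub-sampled so that their SFS matches the
pooled archaic SFS: per frequency bin, the target count is apportioned by
largest-remainder rounding and drawn uniformly without replacement.  Binning
defaults to exact integer allele counts; a fixed-width frequency binning is
available for cohorts with unequal call rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SFS", "build_sfs", "sample_matched_controls", "allocate_largest_remainder"]


@dataclass
class SFS:
    """Histogram over allele counts (``bins`` = count classes) or over
    frequency bins (``edges`` set, bins half-open except the last)."""

    bins: np.ndarray
    counts: np.ndarray
    edges: np.ndarray | None = None
    mode: str = "counts"

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _focal_values(calls: pd.DataFrame, mode: str) -> np.ndarray:
    if mode == "counts":
        vals = calls["focal_count"].to_numpy()
    else:
        vals = calls["miaf"].fillna(calls["daf"]).to_numpy(dtype=float)
    return vals


def build_sfs(calls: pd.DataFrame, mode: str = "counts", n_chrom: int | None = None,
              bin_width: float = 0.02) -> SFS:
    """Histogram the focal allele counts (or frequencies) of a call set.

    ``mode="counts"`` bins by integer allele count (1 .. n_chrom - 1);
    ``mode="freq"`` uses fixed-width frequency bins partitioning [0, 1].
    The bin totals always sum to the number of input calls.
    """
    if mode == "counts":
        if n_chrom is None:
            n_chrom = int(calls["n_chrom"].max()) if len(calls) else 2
        bins = np.arange(1, n_chrom)
        vals = _focal_values(calls, mode)
        counts = np.bincount(
            np.clip(vals, 1, n_chrom - 1).astype(int), minlength=n_chrom
        )[1:n_chrom]
        return SFS(bins=bins, counts=counts, mode="counts")
    if mode == "freq":
        edges = np.arange(0.0, 1.0 + bin_width, bin_width)
        edges[-1] = 1.0
        vals = _focal_values(calls, mode)
        idx = np.clip(np.digitize(vals, edges[1:-1]), 0, len(edges) - 2)
        counts = np.bincount(idx, minlength=len(edges) - 1)
        return SFS(bins=np.arange(len(edges) - 1), counts=counts, edges=edges, mode="freq")
    raise ValueError(f"unknown SFS mode {mode!r}")


def allocate_largest_remainder(weights: np.ndarray, n_total: int) -> np.ndarray:
    """Apportion ``n_total`` across bins proportionally to ``weights`` with
    largest-remainder rounding; the result sums exactly to ``n_total``."""
    weights = np.asarray(weights, dtype=float)
    if weights.sum() == 0:
        return np.zeros_like(weights, dtype=int)
    quota = weights * n_total / weights.sum()
    alloc = np.floor(quota).astype(int)
    short = n_total - alloc.sum()
    if short > 0:
        order = np.argsort(-(quota - alloc), kind="mergesort")
        alloc[order[:short]] += 1
    return alloc


def sample_matched_controls(
    na_calls: pd.DataFrame,
    target_sfs: SFS,
    n_total: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Sub-sample non-archaic calls to match ``target_sfs``.

    ``n_total`` defaults to the target SFS total (the combined archaic
    count); a differing total rescales the per-bin allocation.  Bins with
    fewer available controls than requested contribute everything they have
    (a warning reports the deficit, and the returned set is smaller).
    Deterministic for a fixed seed.
    """
    if n_total is None:
        n_total = target_sfs.total
    rng = np.random.default_rng(seed)
    alloc = allocate_largest_remainder(target_sfs.counts.astype(float), n_total)

    if target_sfs.mode == "counts":
        vals = _focal_values(na_calls, "counts").astype(int)
        bin_of = {int(b): j for j, b in enumerate(target_sfs.bins)}
        bin_idx = np.array([bin_of.get(v, -1) for v in vals])
    else:
        vals = _focal_values(na_calls, "freq")
        edges = target_sfs.edges
        bin_idx = np.clip(np.digitize(vals, edges[1:-1]), 0, len(edges) - 2)

    chosen: list[np.ndarray] = []
    deficit = 0
    for j, want in enumerate(alloc):
        if want == 0:
            continue
        pool = np.flatnonzero(bin_idx == j)
        if len(pool) < want:
            deficit += want - len(pool)
            chosen.append(pool)
        else:
            chosen.append(rng.choice(pool, size=want, replace=False))
    if deficit:
        warnings.warn(
            f"SFS matching shortfall: {deficit} of {n_total} requested controls "
            "unavailable in their bins",
            stacklevel=2,
        )
    if not chosen:
        return na_calls.iloc[:0].copy()
    idx = np.sort(np.concatenate(chosen))
    return na_calls.iloc[idx].copy()
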
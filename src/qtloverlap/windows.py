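"""Local GEBV windows: construction, variance, greedy ranking, permutation.

A local GEBV restricts the genome-wide breeding value to the variants inside
a sliding window (250 kb by default, start grid every 50 kb, anchored at bp 1
per chromosome, half-open [start, start+size)).  The variance of a window's
local GEBV across individuals measures how much genetic variance the window
explains; ranking windows by variance and greedily removing overlaps yields
the non-overlapping interval set whose summed variance is the denominator of
the "var.%" scale (a window's variance as a percentage of that sum).

The within-window effect permutation scrambles which member variant carries
which effect while preserving each window's effect multiset; because windows
overlap, permutation is performed independently per window when computing
that window's permuted local GEBV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bayesr import EffectEstimates
from .synthdata import GenotypeSet, stage_rng

__all__ = [
    "Window",
    "LocalGebvSet",
    "NonOverlapRanking",
    "make_windows",
    "local_gebv",
    "rank_nonoverlapping",
    "permute_effects_within_windows",
    "local_gebv_from_member_effects",
]

WINDOW_SIZE = 250_000
WINDOW_STEP = 50_000


@dataclass(frozen=True)
class Window:
    """Half-open genomic interval [start, end) with its member variant indices."""

    chrom: int
    start: int                     # 1-based
    end: int                       # exclusive
    members: tuple[int, ...]

    def overlaps(self, other: "Window") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass
class LocalGebvSet:
    """Per-window local GEBVs across individuals and their variances."""

    windows: list[Window]
    gebv: np.ndarray               # (W, n_individuals)
    var: np.ndarray                # (W,) sample variance, ddof=1

    def __post_init__(self) -> None:
        if self.gebv.shape[0] != len(self.windows) or len(self.var) != len(self.windows):
            raise ValueError("window count mismatch")
        if np.any(self.var < -1e-12):
            raise ValueError("negative window variance")


@dataclass
class NonOverlapRanking:
    """Greedy non-overlapping windows by descending variance, with var.%."""

    accepted: list[int]            # indices into the LocalGebvSet, acceptance order
    sigma2_sum: float              # sum of accepted window variances
    var_pct: np.ndarray            # per *accepted* window, % of sigma2_sum

    @property
    def u(self) -> int:
        return len(self.accepted)


def make_windows(
    chrom: np.ndarray,
    pos: np.ndarray,
    size: int = WINDOW_SIZE,
    step: int = WINDOW_STEP,
) -> list[Window]:
    """Sliding windows over a sorted variant map; empty windows are dropped.

    Per chromosome, candidate starts are 1 + k*step while start <= the last
    variant position; a variant at position p belongs to windows with
    start <= p < start + size.
    """
    if size % step != 0:
        raise ValueError("size must be a multiple of step")
    windows: list[Window] = []
    for c in np.unique(chrom):
        idx = np.where(chrom == c)[0]
        p = pos[idx]
        start = 1
        while start <= p.max():
            lo = np.searchsorted(p, start, side="left")
            hi = np.searchsorted(p, start + size - 1, side="right")
            if hi > lo:
                windows.append(Window(int(c), start, start + size, tuple(idx[lo:hi])))
            start += step
    return windows


def local_gebv(
    g: GenotypeSet, eff: EffectEstimates, windows: list[Window]
) -> LocalGebvSet:
    """Local GEBV per window: sum of member-dosage x posterior-mean effect."""
    m = g.m_variants
    if len(eff.effects) != m:
        raise ValueError("effects do not align with genotypes")
    gebv = np.empty((len(windows), g.n_individuals))
    for w_i, w in enumerate(windows):
        members = np.asarray(w.members, dtype=int)
        if members.size and members.max() >= m:
            raise ValueError(f"window references unknown variant {members.max()}")
        gebv[w_i] = g.dosages[:, members] @ eff.effects[members]
    var = gebv.var(axis=1, ddof=1) if g.n_individuals > 1 else np.zeros(len(windows))
    return LocalGebvSet(windows, gebv, var)


def local_gebv_from_member_effects(
    g: GenotypeSet, windows: list[Window], member_effects: list[np.ndarray]
) -> LocalGebvSet:
    """Local GEBVs when each window carries its own member-effect vector.

    Used for the within-window permutation, where overlapping windows hold
    independently permuted copies of their member effects.
    """
    gebv = np.empty((len(windows), g.n_individuals))
    for w_i, (w, e) in enumerate(zip(windows, member_effects)):
        members = np.asarray(w.members, dtype=int)
        gebv[w_i] = g.dosages[:, members] @ e
    var = gebv.var(axis=1, ddof=1) if g.n_individuals > 1 else np.zeros(len(windows))
    return LocalGebvSet(windows, gebv, var)


def rank_nonoverlapping(lg: LocalGebvSet) -> NonOverlapRanking:
    """Greedy sweep in descending variance; accept iff no overlap so far.

    Ties on variance break by (chromosome, start) ascending, so the result
    does not depend on the input window ordering.
    """
    if not lg.windows:
        raise ValueError("no windows to rank")
    order = sorted(
        range(len(lg.windows)),
        key=lambda i: (-lg.var[i], lg.windows[i].chrom, lg.windows[i].start),
    )
    accepted: list[int] = []
    for i in order:
        if not any(lg.windows[i].overlaps(lg.windows[j]) for j in accepted):
            accepted.append(i)
    sigma2_sum = float(sum(lg.var[i] for i in accepted))
    if sigma2_sum > 0:
        var_pct = np.array([100.0 * lg.var[i] / sigma2_sum for i in accepted])
    else:
        var_pct = np.zeros(len(accepted))
    return NonOverlapRanking(accepted, sigma2_sum, var_pct)


def permute_effects_within_windows(
    eff: EffectEstimates, windows: list[Window], seed: int = 0
) -> list[np.ndarray]:
    """Independently permute each window's member effects.

    Returns one effect vector per window, aligned with that window's member
    order; each window's effect multiset is preserved exactly.  A variant
    shared by several overlapping windows is permuted separately in each.
    """
    rng = stage_rng(seed, "permute-effects")
    out = []
    for w in windows:
        e = eff.effects[np.asarray(w.members, dtype=int)]
        out.append(rng.permutation(e))
    return out
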
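"""Phylogenetic dispersion of a focal tip set: MPD, MNTD, randomization
nulls, and the NRI/NTI standardized effect sizes.

The question: are the tips in a focal set (here, taxa with coded
morphological characters) spread across the phylogeny at random, clustered,
or overdispersed?  Two community-phylogenetics metrics answer it at
different depths:

* MPD — mean patristic distance over all unordered pairs of focal tips;
  sensitive to structure across the whole tree.
* MNTD — mean, over focal tips, of each tip's distance to its nearest
  *focal* neighbour; sensitive to structure near the tips.

Each observed metric is compared with a null distribution obtained by
drawing the same number of tips uniformly at random (without replacement
within a draw) from the pool, ``reps`` times (default 1000).  The indices

    NRI = -(MPD_obs  - mean(MPD_null))  / sd(MPD_null)
    NTI = -(MNTD_obs - mean(MNTD_null)) / sd(MNTD_null)

are the negated standardized effect sizes: positive values mean the focal
tips are closer together than expected (clustering), negative values mean
overdispersion.  The sd uses the sample (n-1) denominator.  Significance is
a two-tailed rank-based randomization p-value with a +1 continuity
correction, so p is never exactly 0.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field
from typing import Iterable

import dendropy
import numpy as np

from .tree_io import DistanceMatrix, patristic_matrix

logger = logging.getLogger(__name__)

METRICS = ("MPD", "MNTD")
_METRIC_CODE = {"MPD": 1, "MNTD": 2}


def _focal_indices(dm: DistanceMatrix, focal: Iterable[str]) -> np.ndarray:
    focal = set(focal)
    if len(focal) < 2:
        raise ValueError(f"need at least 2 focal tips, got {len(focal)}")
    return dm.indices_of(focal)


def mpd(dm: DistanceMatrix, focal: Iterable[str]) -> float:
    """Mean pairwise patristic distance among the focal tips."""
    idx = _focal_indices(dm, focal)
    sub = dm.values[np.ix_(idx, idx)]
    n = len(idx)
    return float(sub.sum() / (n * (n - 1)))


def mntd(dm: DistanceMatrix, focal: Iterable[str]) -> float:
    """Mean nearest-neighbour patristic distance within the focal tips."""
    idx = _focal_indices(dm, focal)
    sub = dm.values[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def _metric_of_draws(values: np.ndarray, draws: np.ndarray, metric: str) -> np.ndarray:
    """Metric for each row of tip-index draws, vectorized. draws: (reps, n)."""
    sub = values[draws[:, :, None], draws[:, None, :]]  # (reps, n, n)
    n = draws.shape[1]
    if metric == "MPD":
        return sub.sum(axis=(1, 2)) / (n * (n - 1))
    r = np.arange(n)
    sub[:, r, r] = np.inf
    return sub.min(axis=2).mean(axis=1)


@dataclass(frozen=True)
class NullDistribution:
    """Randomization null for one metric at focal-set size ``n``."""

    metric: str
    values: np.ndarray
    n: int
    seed: int | None = None
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "mean", float(vals.mean()))
        # sample sd; a single replicate has no spread by definition
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        # identical replicates can leave summation noise ~1e-16; a null with
        # no real spread must read as degenerate (sd = 0), not near-zero
        if sd <= 1e-12 * max(1.0, abs(self.mean)):
            sd = 0.0
        object.__setattr__(self, "sd", sd)

    @property
    def reps(self) -> int:
        return len(self.values)


def null_distribution(
    dm: DistanceMatrix,
    n: int,
    metric: str,
    reps: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> NullDistribution:
    """Null metric values from ``reps`` uniform draws of ``n`` distinct tips.

    Draws are without replacement within a replicate and independent across
    replicates; reproducible given an integer seed or a Generator.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    T = len(dm)
    if not 2 <= n <= T:
        raise ValueError(f"focal size n={n} out of range [2, {T}]")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    seed = rng if isinstance(rng, int) else None
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    # argsort of uniforms = uniform random permutation per row; first n = draw
    draws = np.argsort(gen.random((reps, T)), axis=1)[:, :n]
    vals = _metric_of_draws(dm.values, draws, metric)
    return NullDistribution(metric, vals, n, seed=seed)


def ses_index(obs: float, null: NullDistribution) -> float:
    """Negated standardized effect size (NRI for MPD, NTI for MNTD).

    NaN when the null has zero spread (e.g. the focal set is the whole
    pool), never +/-inf.
    """
    if null.sd == 0 or not math.isfinite(null.sd):
        return float("nan")
    return -(obs - null.mean) / null.sd


def p_value(obs: float, null: NullDistribution) -> float:
    """Two-tailed randomization p with +1 continuity correction.

    With r = #{null values <= obs}, the lower-tail probability is
    q = (r + 1)/(reps + 1); the returned p is 2 * min(q, 1 - q + 1/(reps+1)),
    capped at 1, so p lies in (0, 1].
    """
    vals = null.values
    reps = len(vals)
    r = int(np.count_nonzero(vals <= obs))
    q = (r + 1) / (reps + 1)
    p = 2 * min(q, 1 - q + 1 / (reps + 1))
    return min(p, 1.0)


@dataclass(frozen=True)
class DispersionResult:
    """Observed MPD/MNTD, NRI/NTI and randomization p-values for one
    clade x level focal set.  Indices and p-values are NaN when the test is
    degenerate (fewer than 2 focal tips in the tree, focal set spans the
    whole pool, or a zero-spread null); ``reason`` says why."""

    clade: str
    level: str
    n: int
    obs_mpd: float
    obs_mntd: float
    nri: float
    nti: float
    p_nri: float
    p_nti: float
    reps: int
    seed: int | None
    reason: str = ""

    @property
    def is_tested(self) -> bool:
        return not (math.isnan(self.nri) and math.isnan(self.nti))


def _substream(seed: int | None, clade: str, level: str, metric: str) -> np.random.Generator:
    """Deterministic per-(clade, level, metric) RNG substream.

    Derived from the top-level seed plus stable CRC32 hashes of the names,
    so adding or reordering clades never shifts another clade's draws.
    """
    entropy = [
        0 if seed is None else int(seed),
        zlib.crc32(clade.encode()),
        zlib.crc32(level.encode()),
        _METRIC_CODE[metric],
    ]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def dispersion_test(
    tree_or_dm: "dendropy.Tree | DistanceMatrix",
    focal: Iterable[str],
    reps: int = 1000,
    seed: int | None = 0,
    clade: str = "",
    level: str = "species",
) -> DispersionResult:
    """Full dispersion test of ``focal`` against the random-draw null.

    The sampling pool is the full tip set of the given tree (or matrix) —
    prune to the clade of interest first.  Results are bit-reproducible for
    a fixed seed; the substream depends on (seed, clade, level, metric).
    """
    dm = tree_or_dm if isinstance(tree_or_dm, DistanceMatrix) else patristic_matrix(tree_or_dm)
    pool = set(dm.labels)
    focal_in = set(focal) & pool
    n = len(focal_in)
    nan = float("nan")

    if n < 2:
        logger.info("dispersion %s/%s: only %d focal tip(s) in pool, not tested",
                    clade, level, n)
        return DispersionResult(clade, level, n, nan, nan, nan, nan, nan, nan,
                                reps, seed, reason="fewer than 2 focal tips in pool")
    obs_mpd = mpd(dm, focal_in)
    obs_mntd = mntd(dm, focal_in)
    if n == len(pool):
        logger.info("dispersion %s/%s: focal set spans the whole pool, indices NA",
                    clade, level)
        return DispersionResult(clade, level, n, obs_mpd, obs_mntd,
                                nan, nan, nan, nan, reps, seed,
                                reason="focal set spans all tips")

    out: dict[str, float] = {}
    for metric, obs in (("MPD", obs_mpd), ("MNTD", obs_mntd)):
        null = null_distribution(dm, n, metric, reps=reps,
                                 rng=_substream(seed, clade, level, metric))
        out[metric] = ses_index(obs, null)
        out["p_" + metric] = p_value(obs, null) if null.sd > 0 else nan
    reason = "zero-spread null" if math.isnan(out["MPD"]) and math.isnan(out["MNTD"]) else ""
    return DispersionResult(clade, level, n, obs_mpd, obs_mntd,
                            out["MPD"], out["MNTD"], out["p_MPD"], out["p_MNTD"],
                            reps, seed, reason=reason)
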
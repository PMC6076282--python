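"""Mark-shuffling null model and pointwise simulation envelopes.

The null hypothesis is that marks are independent of tree locations: shuffle
the (normalized) marks over the trees, recompute the statistic, repeat
``n_sim`` times, and take the rank-th lowest/highest value per distance bin
as the envelope.  With the default 199 replicates and rank 5 the bounds sit
at the pointwise 2.5th and 97.5th percentiles (two-sided level
2*rank/(n_sim+1) = 0.05).  An observed statistic strictly outside the closed
envelope is flagged significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .geometry import MarkedPattern
from .markfuncs import MarkFunctionResult

__all__ = ["EnvelopeConfig", "EnvelopeResult", "shuffle_marks", "build_envelopes", "attach_envelopes"]


@dataclass(frozen=True)
class EnvelopeConfig:
    n_sim: int = 199
    rank: int = 5
    rng_seed: int = 0
    shuffle_scope: str = "global"  # or "within_concession"

    def __post_init__(self) -> None:
        if not (1 <= self.rank <= self.n_sim / 2):
            raise ValueError(f"need 1 <= rank <= n_sim/2, got rank={self.rank}, n_sim={self.n_sim}")
        if self.shuffle_scope not in ("global", "within_concession"):
            raise ValueError(f"unknown shuffle_scope {self.shuffle_scope!r}")

    @property
    def level(self) -> float:
        """Implied pointwise two-sided significance level."""
        return 2 * self.rank / (self.n_sim + 1)


def shuffle_marks(
    marks: np.ndarray,
    scope: str = "global",
    seed=None,
    concession_ids: np.ndarray | None = None,
) -> np.ndarray:
    """Uniformly random permutation of the marks; locations untouched.

    ``scope="within_concession"`` permutes each concession's marks among its
    own trees (requires ``concession_ids``), preserving each concession's
    multiset exactly.  ``seed`` may be an int, SeedSequence or Generator.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    marks = np.asarray(marks, dtype=float)
    if scope == "global":
        return rng.permutation(marks)
    if scope == "within_concession":
        if concession_ids is None:
            raise ValueError("within_concession scope requires concession_ids")
        out = marks.copy()
        for cid in np.unique(concession_ids):
            idx = np.flatnonzero(concession_ids == cid)
            out[idx] = marks[idx][rng.permutation(len(idx))]
        return out
    raise ValueError(f"unknown scope {scope!r}")


@dataclass
class EnvelopeResult:
    observed: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    significant: np.ndarray  # strict exceedance of the closed envelope
    n_valid: np.ndarray  # defined null replicates per bin
    level: float


def build_envelopes(
    stat_fn: Callable[[np.ndarray], np.ndarray],
    pattern: MarkedPattern,
    marks: np.ndarray,
    config: EnvelopeConfig = EnvelopeConfig(),
) -> EnvelopeResult:
    """Pointwise envelopes of ``stat_fn`` under mark shuffling.

    ``stat_fn(marks) -> per-bin array`` must depend on the marks only (fixed
    geometry); the ``fN_plan`` builders in :mod:`markcorr.markfuncs` provide
    exactly this.  Each replicate draws from an independent stream spawned
    from ``config.rng_seed``, so results do not depend on evaluation order.
    Bins where null replicates are undefined (NaN) get bounds from the valid
    replicates only and are reported via ``n_valid``; with fewer than
    ``2*rank`` valid replicates the bounds are NaN.
    """
    marks = np.asarray(marks, dtype=float)
    obs = np.asarray(stat_fn(marks), dtype=float)
    cids = pattern.trees["concession_id"].to_numpy()

    streams = np.random.SeedSequence(config.rng_seed).spawn(config.n_sim)
    sims = np.empty((config.n_sim, obs.size))
    for s, ss in enumerate(streams):
        shuffled = shuffle_marks(marks, config.shuffle_scope, np.random.default_rng(ss), cids)
        sims[s] = stat_fn(shuffled)

    n_valid = (~np.isnan(sims)).sum(axis=0)
    srt = np.sort(sims, axis=0)  # NaNs sort to the end
    lo = np.full(obs.size, np.nan)
    hi = np.full(obs.size, np.nan)
    usable = n_valid >= 2 * config.rank
    cols = np.flatnonzero(usable)
    lo[cols] = srt[config.rank - 1, cols]
    hi[cols] = srt[n_valid[cols] - config.rank, cols]
    with np.errstate(invalid="ignore"):
        significant = (obs < lo) | (obs > hi)
    significant &= ~np.isnan(obs) & usable
    return EnvelopeResult(obs, lo, hi, significant, n_valid, config.level)


def attach_envelopes(result: MarkFunctionResult, env: EnvelopeResult) -> MarkFunctionResult:
    """Write envelope bounds and significance flags into a result table."""
    t = result.table
    t["envelope_lo"] = env.lo
    t["envelope_hi"] = env.hi
    t["significant"] = pd.array(env.significant, dtype="boolean")
    t["n_sim_valid"] = env.n_valid
    return result
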
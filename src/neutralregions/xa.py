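"""X-vs-autosome diversity analysis.

Aggregates mutation-rate-normalized diversity (pi divided by outgroup
divergence) over region sets, forms the X-to-autosome ratio — under
neutrality, equal sex ratios and constant size this estimates Nx/Na with
expectation 3/4 — and the relative ratio between two populations, with
bootstrap standard errors from resampling regions.

Aggregation is a ratio of length-weighted means, not a mean of per-region
ratios: short regions have noisy divergence denominators, and weighting by
length makes the estimate a genome-wide pi over a genome-wide D.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence

import numpy as np

from .records import RegionRecord

__all__ = ["RatioEstimate", "normalized_diversity", "xa_ratio",
           "relative_ratio", "bootstrap_se"]

log = logging.getLogger(__name__)

DEFAULT_REPS = 10_000
DEFAULT_SEED = 20121114
_CHUNK = 2_000  # bootstrap replicates per vectorized block


@dataclasses.dataclass(frozen=True)
class RatioEstimate:
    """A point estimate with its bootstrap standard error."""

    estimate: float
    se: float
    reps: int
    seed: int
    skipped: int = 0  # degenerate (zero-divergence) replicates dropped

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("standard error must be >= 0")
        if self.reps < 1:
            raise ValueError("replicate count must be >= 1")


def _arrays(records: Sequence[RegionRecord], label: str):
    usable = [r for r in records if r.pi is not None and r.div_jc is not None
              and r.div_jc > 0]
    if not usable:
        raise ValueError(
            f"{label}: no region with defined pi and positive JC divergence")
    length = np.array([r.length for r in usable], dtype=float)
    pi_l = np.array([r.pi for r in usable], dtype=float) * length
    d_l = np.array([r.div_jc for r in usable], dtype=float) * length
    return pi_l, d_l, length


def normalized_diversity(records: Sequence[RegionRecord],
                         label: str = "regions") -> float:
    """Length-weighted mean pi over length-weighted mean JC divergence.

    ``(sum pi_i L_i / sum L_i) / (sum D_i L_i / sum L_i)``; regions without
    a defined pi or with non-positive divergence are excluded, and an empty
    usable set is an error.
    """
    pi_l, d_l, _ = _arrays(records, label)
    return float(pi_l.sum() / d_l.sum())


def xa_ratio(x_records: Sequence[RegionRecord],
             a_records: Sequence[RegionRecord]) -> float:
    """Normalized X diversity over normalized autosomal diversity (Nx/Na
    estimator; neutral expectation 0.75)."""
    return normalized_diversity(x_records, "X") / normalized_diversity(a_records, "autosomes")


def relative_ratio(pop1_xa: float, pop2_xa: float) -> float:
    """Ratio of two populations' Nx/Na estimates."""
    if pop2_xa == 0:
        raise ZeroDivisionError("second population's X/A ratio is zero")
    return pop1_xa / pop2_xa


def bootstrap_se(x_records: Sequence[RegionRecord],
                 a_records: Sequence[RegionRecord],
                 reps: int = DEFAULT_REPS,
                 seed: Optional[int] = None) -> RatioEstimate:
    """Bootstrap standard error of the X/A ratio.

    X and autosomal regions are resampled independently, with replacement,
    at their original counts; the ratio is recomputed per replicate and the
    SE is the standard deviation across replicates.  Deterministic given
    ``seed`` (the default seed is fixed and logged).  Replicates whose
    resampled divergence sums to zero in either stratum cannot form a ratio
    and are dropped (counted in ``skipped``).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if seed is None:
        seed = DEFAULT_SEED
    log.info("bootstrap: %d replicates, seed %d", reps, seed)
    point = xa_ratio(x_records, a_records)
    x_pi, x_d, _ = _arrays(x_records, "X")
    a_pi, a_d, _ = _arrays(a_records, "autosomes")
    rng = np.random.default_rng(seed)
    ratios: list[np.ndarray] = []
    skipped = 0
    done = 0
    while done < reps:
        k = min(_CHUNK, reps - done)
        xi = rng.integers(0, len(x_pi), size=(k, len(x_pi)))
        ai = rng.integers(0, len(a_pi), size=(k, len(a_pi)))
        x_num, x_den = x_pi[xi].sum(axis=1), x_d[xi].sum(axis=1)
        a_num, a_den = a_pi[ai].sum(axis=1), a_d[ai].sum(axis=1)
        good = (x_den > 0) & (a_den > 0) & (a_num > 0)
        n_bad = int((~good).sum())
        if n_bad:
            log.warning("dropping %d degenerate bootstrap replicates", n_bad)
            skipped += n_bad
        ratios.append((x_num[good] / x_den[good]) / (a_num[good] / a_den[good]))
        done += k
    values = np.concatenate(ratios)
    se = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return RatioEstimate(estimate=point, se=se, reps=reps, seed=seed,
                         skipped=skipped)
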
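"""Minority oversampling by per-dimension feature resampling with a
class-center distance filter.

New minority candidates are assembled coordinate-by-coordinate: the value of
dimension j is drawn uniformly from the multiset of minority values observed
on dimension j.  This keeps every synthetic coordinate inside the observed
minority marginal support while producing novel combinations, which adds
diversity without interpolating through majority territory the way
nearest-neighbour schemes can.

Because independent per-dimension draws can also produce outliers, each
candidate x is kept only if it is ordered correctly with respect to the
three class centers in embedding space:

    d(x, C_maj) > d(x, C_all) > d(x, C_min)       (strict, Euclidean)

i.e. the candidate must sit closer to the minority center than to the
overall center, and closer to the overall center than to the majority
center.  Candidates failing the chain are discarded.  Enough candidates are
accepted to bring the minority count up to the majority count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Centers",
    "FeaturePool",
    "SynthesisReport",
    "compute_centers",
    "build_feature_pool",
    "synthesize_candidate",
    "passes_center_filter",
    "oversample_to_balance",
]


@dataclass(frozen=True)
class Centers:
    """Minority, majority and overall arithmetic mean vectors."""

    c_min: np.ndarray
    c_maj: np.ndarray
    c_all: np.ndarray


@dataclass(frozen=True)
class FeaturePool:
    """Per-dimension multisets of minority values, stored as an (n_min, d) array.

    Column j of ``values`` is the multiset F_j of minority-sample values on
    dimension j.
    """

    values: np.ndarray

    @property
    def n_min(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SynthesisReport:
    requested: int
    accepted: int
    rejected: int
    attempts: int
    fallback_used: int

    def to_dict(self) -> dict:
        return {
            "requested": self.requested,
            "accepted": self.accepted,
            "rejected": self.rejected,
            "attempts": self.attempts,
            "fallback_used": self.fallback_used,
        }


def compute_centers(Z: np.ndarray, y: np.ndarray) -> Centers:
    """Class centers in embedding space: minority, majority and overall means."""
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y)
    minority = Z[y == 1]
    majority = Z[y == -1]
    if len(minority) == 0 or len(majority) == 0:
        raise ValueError("both classes must be present to compute centers")
    return Centers(
        c_min=minority.mean(axis=0),
        c_maj=majority.mean(axis=0),
        c_all=Z.mean(axis=0),
    )


def build_feature_pool(Z: np.ndarray, y: np.ndarray) -> FeaturePool:
    """Collect the minority values of every dimension; needs n_min >= 2."""
    Z = np.asarray(Z, dtype=float)
    minority = Z[np.asarray(y) == 1]
    if len(minority) < 2:
        raise ValueError("feature pool needs at least 2 minority samples")
    return FeaturePool(values=minority.copy())


def synthesize_candidate(pool: FeaturePool, rng: np.random.Generator) -> np.ndarray:
    """Draw one candidate, coordinate j uniform from F_j, independently."""
    rows = rng.integers(0, pool.n_min, size=pool.dim)
    return pool.values[rows, np.arange(pool.dim)]


def passes_center_filter(x: np.ndarray, centers: Centers) -> bool:
    """Strict inequality chain d(x,C_maj) > d(x,C_all) > d(x,C_min); ties reject."""
    x = np.asarray(x, dtype=float)
    d_maj = np.linalg.norm(x - centers.c_maj)
    d_all = np.linalg.norm(x - centers.c_all)
    d_min = np.linalg.norm(x - centers.c_min)
    return bool(d_maj > d_all > d_min)


def _candidate_block(pool: FeaturePool, rng: np.random.Generator, count: int) -> np.ndarray:
    rows = rng.integers(0, pool.n_min, size=(count, pool.dim))
    return pool.values[rows, np.arange(pool.dim)]


def oversample_to_balance(
    Z: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    max_attempt_factor: int = 200,
):
    """Append filtered synthetic minority rows until class counts are equal.

    Original rows are preserved verbatim and come first in the output; all
    synthetic rows carry label +1.  Candidate generation is rejection
    sampling against the center filter, capped at
    ``max_attempt_factor * deficit`` attempts.  If the cap is exhausted (the
    filter acceptance region can be empty for pathological geometries), the
    remaining deficit is filled by jittered duplication of random minority
    rows (Gaussian noise with sigma = 1% of the per-dimension minority
    range); those rows are counted in ``fallback_used``.

    Returns ``(Z_bal, y_bal, SynthesisReport)``.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y)
    n_min = int(np.sum(y == 1))
    n_maj = int(np.sum(y == -1))
    if n_min == 0 or n_maj == 0:
        raise ValueError("both classes must be present")
    deficit = n_maj - n_min
    if deficit <= 0:
        return Z.copy(), y.copy(), SynthesisReport(0, 0, 0, 0, 0)

    centers = compute_centers(Z, y)
    pool = build_feature_pool(Z, y)
    max_attempts = max_attempt_factor * deficit

    accepted_rows: list[np.ndarray] = []
    attempts = 0
    block = max(64, deficit)
    while len(accepted_rows) < deficit and attempts < max_attempts:
        count = min(block, max_attempts - attempts)
        cands = _candidate_block(pool, rng, count)
        d_maj = np.linalg.norm(cands - centers.c_maj, axis=1)
        d_all = np.linalg.norm(cands - centers.c_all, axis=1)
        d_min = np.linalg.norm(cands - centers.c_min, axis=1)
        ok = (d_maj > d_all) & (d_all > d_min)
        needed = deficit - len(accepted_rows)
        ok_idx = np.flatnonzero(ok)
        if len(ok_idx) >= needed:
            # count only the examined prefix so attempts = accepted + rejected
            last = ok_idx[needed - 1]
            attempts += last + 1
            accepted_rows.extend(cands[ok_idx[:needed]])
        else:
            attempts += count
            accepted_rows.extend(cands[ok_idx])
    accepted = len(accepted_rows)
    rejected = attempts - accepted

    fallback = deficit - accepted
    if fallback > 0:
        minority = pool.values
        span = minority.max(axis=0) - minority.min(axis=0)
        donors = rng.integers(0, len(minority), size=fallback)
        jitter = rng.normal(scale=0.01 * span, size=(fallback, minority.shape[1]))
        accepted_rows.extend(minority[donors] + jitter)

    Z_bal = np.vstack([Z] + [np.asarray(accepted_rows)]) if accepted_rows else Z.copy()
    y_bal = np.concatenate([y, np.ones(deficit, dtype=y.dtype)])
    report = SynthesisReport(
        requested=deficit,
        accepted=accepted,
        rejected=rejected,
        attempts=attempts,
        fallback_used=fallback,
    )
    return Z_bal, y_bal, report
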
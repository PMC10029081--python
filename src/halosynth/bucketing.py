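"""Discretization of continuous clinical variables into bucket codes.

Lab values and inter-visit gaps are continuous, but the generative model
works on binary code vectors.  Each continuous variable is therefore split
into a small number of value *buckets*; every bucket owns a binary code in
the vocabulary, and a value is represented by switching on the code of the
bucket it falls into.  After generation, a bucket code is converted back to
a number by sampling uniformly within the bucket's bounds.

Interval convention: buckets are half-open ``[b_k, b_{k+1})``; the last
bucket is closed on the right so that the configured range is tiled exactly.
Bucket indices are 0-based throughout the package.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["BucketSpec", "fit_buckets", "bucket_index", "bucket_sample"]


@dataclass(frozen=True)
class BucketSpec:
    """Bucketing scheme for one continuous variable.

    Parameters
    ----------
    variable_id
        Name of the variable (a lab id, or ``"gap"`` for inter-visit gaps).
    bounds
        Strictly increasing boundary values.  ``len(bounds) - 1`` buckets are
        defined as half-open intervals ``[bounds[k], bounds[k+1])``, the last
        one closed on the right.
    strategy
        How the bounds were obtained: ``uniform``, ``quantile`` or
        ``explicit``.
    code_ids
        One vocabulary code per bucket, in bucket order.
    """

    variable_id: str
    bounds: tuple[float, ...]
    strategy: str = "explicit"
    code_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        b = np.asarray(self.bounds, dtype=float)
        if b.size < 2:
            raise ValueError(f"{self.variable_id}: need at least 2 boundaries")
        if not np.all(np.diff(b) > 0):
            raise ValueError(f"{self.variable_id}: bounds must be strictly increasing")
        if self.code_ids and len(self.code_ids) != self.n_buckets:
            raise ValueError(
                f"{self.variable_id}: {len(self.code_ids)} code_ids for "
                f"{self.n_buckets} buckets"
            )

    @property
    def n_buckets(self) -> int:
        return len(self.bounds) - 1

    def with_codes(self, code_ids: Sequence[str]) -> "BucketSpec":
        return BucketSpec(self.variable_id, self.bounds, self.strategy, tuple(code_ids))

    def to_dict(self) -> dict:
        return {
            "variable_id": self.variable_id,
            "bounds": list(self.bounds),
            "strategy": self.strategy,
            "code_ids": list(self.code_ids),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BucketSpec":
        return cls(
            d["variable_id"], tuple(d["bounds"]), d.get("strategy", "explicit"),
            tuple(d.get("code_ids", ())),
        )


def default_code_ids(variable_id: str, n_buckets: int) -> tuple[str, ...]:
    """Canonical bucket-code naming: ``<variable>:bucket<k>``."""
    return tuple(f"{variable_id}:bucket{k}" for k in range(n_buckets))


def fit_buckets(
    values: Sequence[float],
    n_buckets: int,
    strategy: str = "uniform",
    variable_id: str = "var",
    bounds: Sequence[float] | None = None,
) -> BucketSpec:
    """Construct a :class:`BucketSpec` from observed values.

    ``uniform`` partitions ``[min, max]`` into equal-width buckets;
    ``quantile`` places boundaries at equal-frequency points of the sample;
    ``explicit`` passes caller-supplied ``bounds`` through unchanged.
    Under ``quantile``, if the sample has fewer distinct boundary points than
    requested the bucket count is reduced with a warning.
    """
    if strategy == "explicit":
        if bounds is None:
            raise ValueError("explicit strategy requires bounds")
        spec = BucketSpec(variable_id, tuple(float(b) for b in bounds), "explicit")
        return spec.with_codes(default_code_ids(variable_id, spec.n_buckets))

    if n_buckets < 1:
        raise ValueError("n_buckets must be >= 1")
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("values must be non-empty")

    if strategy == "uniform":
        lo, hi = float(vals.min()), float(vals.max())
        if lo == hi:
            hi = lo + 1.0  # degenerate sample: a single unit-width bucket range
        edges = np.linspace(lo, hi, n_buckets + 1)
    elif strategy == "quantile":
        qs = np.linspace(0.0, 1.0, n_buckets + 1)
        edges = np.unique(np.quantile(vals, qs))
        if edges.size < 2:
            edges = np.array([edges[0], edges[0] + 1.0])
        if edges.size < n_buckets + 1:
            warnings.warn(
                f"{variable_id}: only {edges.size - 1} distinct quantile buckets "
                f"available (requested {n_buckets})",
                stacklevel=2,
            )
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    spec = BucketSpec(variable_id, tuple(float(e) for e in edges), strategy)
    return spec.with_codes(default_code_ids(variable_id, spec.n_buckets))


def bucket_index(value: float, spec: BucketSpec, clamp: bool = False) -> int:
    """Return the 0-based bucket index containing ``value``.

    Buckets are half-open on the right except the last, which is closed so
    the maximum bound is representable.  Out-of-range values raise unless
    ``clamp`` is set, in which case they map to the extreme bucket.
    """
    b = spec.bounds
    if value < b[0] or value > b[-1]:
        if clamp:
            return 0 if value < b[0] else spec.n_buckets - 1
        raise ValueError(
            f"{spec.variable_id}: value {value} outside [{b[0]}, {b[-1]}]"
        )
    k = int(np.searchsorted(b, value, side="right")) - 1
    return min(k, spec.n_buckets - 1)


def bucket_sample(k: int, spec: BucketSpec, rng: np.random.Generator) -> float:
    """Draw a value uniformly from bucket ``k`` of ``spec``."""
    if not 0 <= k < spec.n_buckets:
        raise ValueError(f"bucket index {k} out of range for {spec.variable_id}")
    return float(rng.uniform(spec.bounds[k], spec.bounds[k + 1]))
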
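"""Patient records and their binary matrix representation.

A patient record is a set of static labels plus an ordered list of visits;
each visit holds a set of medical codes, optional lab values, and the time
gap (in days) since the previous visit.  For modeling, a record is encoded
as a binary matrix with one row per "visit" in an extended sense:

    row 0            start row (one-hot at the start code)
    row 1            label row (static demographic / phenotype codes)
    rows 2 .. T+1    the T clinical visits (multi-hot)
    row T+2          end row (one-hot at the end code)
    rows T+3 ..      all-zero padding up to a constant length

Continuous values (labs, gaps) are bucket-encoded into their bucket codes on
the visit rows; decoding draws a uniform value within the bucket bounds.
The gap code on a visit row describes the gap *preceding* that visit, so the
first visit never carries one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .bucketing import BucketSpec, bucket_index, bucket_sample
from .vocab import Vocabulary

GAP_VARIABLE = "gap"

__all__ = [
    "Visit",
    "PatientRecord",
    "RecordMatrix",
    "encode_record",
    "decode_record",
    "encode_cohort",
    "GAP_VARIABLE",
]


@dataclass
class Visit:
    codes: set[str] = field(default_factory=set)
    labs: dict[str, float] = field(default_factory=dict)
    gap_days: float | None = None

    def __post_init__(self) -> None:
        if self.gap_days is not None:
            g = float(self.gap_days)
            if not np.isfinite(g) or g < 0:
                raise ValueError(f"gap_days must be finite and >= 0, got {g}")
            self.gap_days = g


@dataclass
class PatientRecord:
    labels: set[str] = field(default_factory=set)
    visits: list[Visit] = field(default_factory=list)

    @property
    def n_visits(self) -> int:
        return len(self.visits)

    def all_codes(self) -> set[str]:
        """Union of label codes and medical codes over all visits."""
        out = set(self.labels)
        for v in self.visits:
            out |= v.codes
        return out


@dataclass
class RecordMatrix:
    """Binary matrix form of one record, padded to a constant row count."""

    bits: np.ndarray  # (max_T + 3, |C|), uint8
    valid_rows: np.ndarray  # (max_T + 3,), uint8
    T: int

    def validate(self, vocab: Vocabulary) -> None:
        """Check every structural invariant; raise ``ValueError`` on violation."""
        bits, valid = self.bits, self.valid_rows
        n_valid = int(valid.sum())
        if n_valid != self.T + 3:
            raise ValueError(f"expected {self.T + 3} valid rows, found {n_valid}")
        if not np.all(valid[: self.T + 3] == 1) or not np.all(valid[self.T + 3 :] == 0):
            raise ValueError("valid rows must be a contiguous prefix")
        start_row = np.zeros(len(vocab), dtype=np.uint8)
        start_row[vocab.start_index] = 1
        if not np.array_equal(bits[0], start_row):
            raise ValueError("row 0 must be one-hot at the start code")
        label_pos = set(vocab.label_positions.tolist())
        on = np.flatnonzero(bits[1])
        if not set(on.tolist()) <= label_pos:
            raise ValueError("row 1 may only contain label-category bits")
        if bits[self.T + 2, vocab.end_index] != 1:
            raise ValueError("final valid row must carry the end code")
        if np.any(bits[self.T + 3 :]):
            raise ValueError("padded rows must be all-zero")


def _bucket_positions(spec: BucketSpec, vocab: Vocabulary) -> np.ndarray:
    return np.array([vocab.index_of[c] for c in spec.code_ids], dtype=np.int64)


def encode_record(
    record: PatientRecord,
    vocab: Vocabulary,
    bucket_specs: Sequence[BucketSpec] = (),
    max_T: int | None = None,
    clamp: bool = False,
) -> RecordMatrix:
    """Encode a :class:`PatientRecord` into its padded binary matrix.

    ``bucket_specs`` supplies one :class:`BucketSpec` per continuous
    variable; the spec with ``variable_id == "gap"`` handles inter-visit
    gaps.  ``clamp`` forwards to :func:`bucket_index` for out-of-range
    values.
    """
    T = record.n_visits
    if max_T is None:
        max_T = T
    if T > max_T:
        raise ValueError(f"record has {T} visits, exceeding max_T={max_T}")
    C = len(vocab)
    specs = {s.variable_id: s for s in bucket_specs}
    bits = np.zeros((max_T + 3, C), dtype=np.uint8)
    bits[0, vocab.start_index] = 1
    for code in record.labels:
        if code not in vocab:
            raise KeyError(f"unknown label code {code!r}")
        if vocab.category(code) != "label":
            raise ValueError(f"{code!r} is not a label-category code")
        bits[1, vocab.index_of[code]] = 1
    for t, visit in enumerate(record.visits):
        row = 2 + t
        for code in visit.codes:
            if code not in vocab:
                raise KeyError(f"unknown medical code {code!r}")
            bits[row, vocab.index_of[code]] = 1
        for lab_id, value in visit.labs.items():
            if lab_id not in specs:
                raise KeyError(f"no bucket spec for lab {lab_id!r}")
            spec = specs[lab_id]
            k = bucket_index(float(value), spec, clamp=clamp)
            bits[row, vocab.index_of[spec.code_ids[k]]] = 1
        if t >= 1 and visit.gap_days is not None and GAP_VARIABLE in specs:
            spec = specs[GAP_VARIABLE]
            k = bucket_index(float(visit.gap_days), spec, clamp=clamp)
            bits[row, vocab.index_of[spec.code_ids[k]]] = 1
    bits[T + 2, vocab.end_index] = 1
    valid = np.zeros(max_T + 3, dtype=np.uint8)
    valid[: T + 3] = 1
    return RecordMatrix(bits=bits, valid_rows=valid, T=T)


def decode_record(
    matrix: RecordMatrix,
    vocab: Vocabulary,
    bucket_specs: Sequence[BucketSpec] = (),
    rng: np.random.Generator | None = None,
) -> PatientRecord:
    """Invert :func:`encode_record` up to bucket resolution.

    Bucket codes become values drawn uniformly within their bucket bounds,
    so a decode is exact on code sets and labels and stochastic (within
    known bounds) on continuous values.
    """
    matrix.validate(vocab)
    if rng is None:
        rng = np.random.default_rng()
    specs = list(bucket_specs)
    label_codes = [
        vocab.entries[i][0] for i in np.flatnonzero(matrix.bits[1])
    ]
    record = PatientRecord(labels=set(label_codes))
    spec_positions = [(s, _bucket_positions(s, vocab)) for s in specs]
    for t in range(matrix.T):
        row = matrix.bits[2 + t]
        on = np.flatnonzero(row)
        visit = Visit()
        handled = np.zeros(len(vocab), dtype=bool)
        for spec, pos in spec_positions:
            hits = pos[row[pos] == 1]
            if hits.size > 1:
                raise ValueError(
                    f"visit row {2 + t}: multiple bucket codes set for "
                    f"variable {spec.variable_id!r}"
                )
            if hits.size == 1:
                k = int(np.where(pos == hits[0])[0][0])
                value = bucket_sample(k, spec, rng)
                if spec.variable_id == GAP_VARIABLE:
                    visit.gap_days = value
                else:
                    visit.labs[spec.variable_id] = value
                handled[hits[0]] = True
        for i in on:
            if handled[i]:
                continue
            code, cat = vocab.entries[i]
            if cat == "medical":
                visit.codes.add(code)
            elif cat in ("gap_bucket", "lab_bucket"):
                raise ValueError(
                    f"visit row {2 + t}: bucket code {code!r} has no spec"
                )
            else:
                raise ValueError(f"visit row {2 + t}: unexpected {cat} code {code!r}")
        record.visits.append(visit)
    return record


def encode_cohort(
    cohort: Sequence[PatientRecord],
    vocab: Vocabulary,
    bucket_specs: Sequence[BucketSpec] = (),
    max_T: int | None = None,
    clamp: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Encode a cohort into stacked ``(bits, valid_rows)`` arrays.

    Returns float/uint8 arrays of shape ``(n, max_T + 3, |C|)`` and
    ``(n, max_T + 3)``.  ``max_T`` defaults to the longest record.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    if max_T is None:
        max_T = max(r.n_visits for r in cohort)
    mats = [encode_record(r, vocab, bucket_specs, max_T, clamp=clamp) for r in cohort]
    bits = np.stack([m.bits for m in mats])
    valid = np.stack([m.valid_rows for m in mats])
    return bits, valid
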
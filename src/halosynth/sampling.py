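"""Autoregressive generation of synthetic records.

Rows are generated in order (label row first, then visit rows) and, within a
row, codes are sampled one at a time in vocabulary order, each Bernoulli
draw conditioned on the history of completed rows and the codes already
sampled in the current row.  Generation of a record stops at the first
sampled row containing the end code (that row becomes a clean end row) or
when the visit capacity is reached, in which case an end row is appended.

Sampling restricts which positions may switch on per row: the label row
samples only label-category positions; visit rows sample medical, bucket
and end positions.  A repair step keeps at most one bucket code per
continuous variable per row (the one with the highest model probability),
since independent Bernoulli draws cannot enforce that constraint
themselves.

Reproducibility: each record owns a generator spawned from the cohort seed
and consumes exactly one uniform vector per sampled row, so results do not
depend on internal batching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .bucketing import BucketSpec
from .network import HALONetwork
from .records import PatientRecord, RecordMatrix, decode_record
from .vocab import Vocabulary

__all__ = ["GenerationSpec", "sample_visit_row", "sample_record", "sample_cohort",
           "sample_matrices"]


@dataclass
class GenerationSpec:
    """What to generate: cohort size, conditioning, length cap, seed."""

    n_records: int
    condition_labels: frozenset[str] | None = None
    max_T: int | None = None
    seed: int = 0
    temperature: float = 1.0

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


# ---------------------------------------------------------------------------
# row-level sampling
# ---------------------------------------------------------------------------

def _fine_row_sample(net: HALONetwork, h: np.ndarray, u: np.ndarray,
                     allowed: np.ndarray, pinned: np.ndarray,
                     temperature: float) -> tuple[np.ndarray, np.ndarray]:
    """Sample one row for a batch given history vectors ``h`` (B, n_emb).

    ``u`` is the per-record uniform vector (B, C); ``allowed`` marks
    positions that may be sampled; ``pinned`` holds -1 (free) or a forced
    bit.  Returns (bits, probs), both (B, C).
    """
    cfg = net.config
    E, C = cfg.n_emb, net.n_codes
    p = net.params
    B = h.shape[0]
    bits = np.zeros((B, C))
    probs = np.zeros((B, C))

    if cfg.N == 2:
        W1 = p["fine0.W"] * net.fine_masks[0]
        b1 = p["fine0.b"]
        W2 = p["fine1.W"] * net.fine_masks[1]
        b2 = p["fine1.b"]
        z_pre = h @ W1[:E, :] + b1  # code bits all zero initially
        for i in range(C):
            col = E + i
            logit = np.maximum(z_pre, 0.0) @ W2[:, col] + b2[col]
            prob = 1.0 / (1.0 + np.exp(-logit / temperature))
            probs[:, i] = prob
            bit = (u[:, i] < prob).astype(np.float64)
            if not allowed[i]:
                bit[:] = 0.0
            forced = pinned[:, i] >= 0
            bit[forced] = pinned[forced, i]
            on = bit > 0
            if on.any():
                z_pre[on] += W1[col]
            bits[:, i] = bit
    else:
        # generic path: full fine-stack forward per code
        x = np.zeros((B, E + C))
        x[:, :E] = h
        for i in range(C):
            col = E + i
            z = x
            for n in range(cfg.N):
                w_eff = p[f"fine{n}.W"] * net.fine_masks[n]
                z_new = z @ w_eff + p[f"fine{n}.b"]
                z = np.maximum(z_new, 0.0) if n < cfg.N - 1 else z_new
            prob = 1.0 / (1.0 + np.exp(-z[:, col] / temperature))
            probs[:, i] = prob
            bit = (u[:, i] < prob).astype(np.float64)
            if not allowed[i]:
                bit[:] = 0.0
            forced = pinned[:, i] >= 0
            bit[forced] = pinned[forced, i]
            x[:, col] = bit
            bits[:, i] = bit
    return bits, probs


def _coarse_row_sample(net: HALONetwork, h: np.ndarray, u: np.ndarray,
                       allowed: np.ndarray, pinned: np.ndarray,
                       temperature: float) -> tuple[np.ndarray, np.ndarray]:
    logits = (h @ net.params["coarse.W"] + net.params["coarse.b"]) / temperature
    probs = 1.0 / (1.0 + np.exp(-logits))
    bits = (u < probs).astype(np.float64)
    bits[:, ~allowed] = 0.0
    forced = pinned >= 0
    bits[forced] = pinned[forced]
    return bits, probs


def sample_visit_row(
    net: HALONetwork,
    prefix: np.ndarray,
    rng: np.random.Generator,
    temperature: float = 1.0,
    allowed: np.ndarray | None = None,
    pinned: np.ndarray | None = None,
) -> np.ndarray:
    """Sample the next row given ``prefix`` (rows already generated, (r, C)).

    Codes are drawn one at a time in vocabulary order, each conditioned on
    the prefix and the codes already drawn in this row.
    """
    prefix = np.asarray(prefix, dtype=np.float64)
    if prefix.ndim != 2 or prefix.shape[0] < 1:
        raise ValueError("prefix must contain at least the start row")
    if prefix.shape[0] >= net.config.seq_len:
        raise ValueError("prefix already at maximum length")
    C = net.n_codes
    if allowed is None:
        allowed = np.ones(C, dtype=bool)
    if pinned is None:
        pinned = -np.ones((1, C))
    H = net.visit_histories(prefix[None])
    h = H[:, -1, :]
    u = rng.random(C)[None]
    fn = _coarse_row_sample if net.config.coarse else _fine_row_sample
    bits, _ = fn(net, h, u, allowed, pinned, temperature)
    return bits[0]


# ---------------------------------------------------------------------------
# record / cohort sampling
# ---------------------------------------------------------------------------

def _allowed_masks(vocab: Vocabulary) -> tuple[np.ndarray, np.ndarray]:
    C = len(vocab)
    label_allowed = np.zeros(C, dtype=bool)
    label_allowed[vocab.label_positions] = True
    visit_allowed = np.zeros(C, dtype=bool)
    visit_allowed[vocab.positions_of("medical", "gap_bucket", "lab_bucket")] = True
    visit_allowed[vocab.end_index] = True
    return label_allowed, visit_allowed


def _bucket_repair(bits: np.ndarray, probs: np.ndarray,
                   bucket_positions: Sequence[np.ndarray]) -> None:
    """Keep only the highest-probability bucket per variable in each row."""
    for pos in bucket_positions:
        sub = bits[:, pos]
        multi = sub.sum(axis=1) > 1
        if not multi.any():
            continue
        for r in np.flatnonzero(multi):
            on = pos[sub[r] > 0]
            keep = on[np.argmax(probs[r, on])]
            bits[r, pos] = 0.0
            bits[r, keep] = 1.0


def sample_matrices(
    net: HALONetwork,
    vocab: Vocabulary,
    spec: GenerationSpec,
    bucket_specs: Sequence[BucketSpec] = (),
    rngs: Sequence[np.random.Generator] | None = None,
    batch_size: int = 512,
) -> tuple[list[RecordMatrix], list[np.random.Generator]]:
    """Generate ``spec.n_records`` record matrices.

    Returns the matrices and the per-record generators (which callers may
    reuse, e.g. to decode bucket codes with the same stream).
    """
    if len(vocab) != net.n_codes:
        raise ValueError("vocabulary size does not match network")
    max_T = spec.max_T if spec.max_T is not None else net.config.max_T
    if max_T > net.config.max_T:
        raise ValueError(f"max_T={max_T} exceeds network capacity {net.config.max_T}")
    C = len(vocab)
    L = max_T + 3
    if rngs is None:
        rngs = [np.random.default_rng(s)
                for s in np.random.SeedSequence(spec.seed).spawn(spec.n_records)]
    label_allowed, visit_allowed = _allowed_masks(vocab)

    cond_pinned = -np.ones(C)
    if spec.condition_labels is not None:
        for code in spec.condition_labels:
            if code not in vocab or vocab.category(code) != "label":
                raise KeyError(f"condition label {code!r} not a label code")
        cond_pinned[vocab.label_positions] = 0.0
        for code in spec.condition_labels:
            cond_pinned[vocab.index_of[code]] = 1.0

    spec_positions = [
        np.array([vocab.index_of[c] for c in bs.code_ids], dtype=np.int64)
        for bs in bucket_specs
    ]

    matrices: list[RecordMatrix] = [None] * spec.n_records  # type: ignore
    sample_fn = _coarse_row_sample if net.config.coarse else _fine_row_sample

    for lo in range(0, spec.n_records, batch_size):
        idx = list(range(lo, min(lo + batch_size, spec.n_records)))
        B = len(idx)
        bits = np.zeros((B, L, C))
        bits[:, 0, vocab.start_index] = 1.0
        T_of = np.full(B, -1, dtype=int)  # -1: still generating
        # label row
        u = np.stack([rngs[i].random(C) for i in idx])
        H = net.visit_histories(bits[:, :1, :])
        pinned = np.tile(cond_pinned, (B, 1))
        row, _ = sample_fn(net, H[:, -1, :], u, label_allowed, pinned,
                           spec.temperature)
        bits[:, 1, :] = row
        # visit rows
        active = np.arange(B)
        for r in range(2, L):
            if active.size == 0:
                break
            u = np.stack([rngs[idx[a]].random(C) for a in active])
            H = net.visit_histories(bits[active, :r, :])
            pinned = -np.ones((active.size, C))
            row, probs = sample_fn(net, H[:, -1, :], u, visit_allowed, pinned,
                                   spec.temperature)
            if r == L - 1:
                # capacity reached: force an end row
                row[:] = 0.0
                row[:, vocab.end_index] = 1.0
            else:
                ended = row[:, vocab.end_index] > 0
                if ended.any():
                    row[ended] = 0.0
                    row[ended, vocab.end_index] = 1.0
                if spec_positions:
                    live = np.flatnonzero(~ended)
                    if live.size:
                        sub = row[live]
                        _bucket_repair(sub, probs[live], spec_positions)
                        row[live] = sub
            bits[active, r, :] = row
            finished = row[:, vocab.end_index] > 0
            T_of[active[finished]] = r - 2
            active = active[~finished]
        for b, i in enumerate(idx):
            T = int(T_of[b])
            valid = np.zeros(L, dtype=np.uint8)
            valid[: T + 3] = 1
            m = RecordMatrix(bits=bits[b].astype(np.uint8), valid_rows=valid, T=T)
            m.validate(vocab)
            matrices[i] = m
    return matrices, list(rngs)


def sample_record(
    net: HALONetwork,
    vocab: Vocabulary,
    spec: GenerationSpec,
    rng: np.random.Generator,
    bucket_specs: Sequence[BucketSpec] = (),
) -> RecordMatrix:
    """Generate a single record matrix using the supplied generator."""
    one = GenerationSpec(1, spec.condition_labels, spec.max_T, spec.seed,
                         spec.temperature)
    mats, _ = sample_matrices(net, vocab, one, bucket_specs, rngs=[rng])
    return mats[0]


def sample_cohort(
    net: HALONetwork,
    vocab: Vocabulary,
    spec: GenerationSpec,
    bucket_specs: Sequence[BucketSpec] = (),
) -> list[PatientRecord]:
    """Generate and decode a cohort of patient records; fully reproducible."""
    mats, rngs = sample_matrices(net, vocab, spec, bucket_specs)
    return [decode_record(m, vocab, bucket_specs, rng=r)
            for m, r in zip(mats, rngs)]
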
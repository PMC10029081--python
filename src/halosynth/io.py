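"""Cohort file I/O and model checkpoints.

Cohort interchange format: one JSON object per line, streaming-friendly:

    {"labels": ["L0"], "visits": [{"codes": ["C001"], "labs": {"lab_hr": 82.5},
                                   "gap_days": null}, ...]}

Serialization is deterministic (sorted labels/codes, stable field order)
so identical cohorts produce byte-identical files; lab values keep full
precision.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np

from .records import PatientRecord, Visit

__all__ = ["read_cohort", "write_cohort", "save_checkpoint", "load_checkpoint"]


class CohortFormatError(ValueError):
    """Raised for malformed cohort files; message names the offending line."""


def _record_to_obj(record: PatientRecord) -> dict:
    return {
        "labels": sorted(record.labels),
        "visits": [
            {
                "codes": sorted(v.codes),
                "labs": {k: v.labs[k] for k in sorted(v.labs)},
                "gap_days": v.gap_days,
            }
            for v in record.visits
        ],
    }


def _obj_to_record(obj: dict, lineno: int) -> PatientRecord:
    if not isinstance(obj, dict):
        raise CohortFormatError(f"line {lineno}: expected a JSON object")
    for key in ("labels", "visits"):
        if key not in obj:
            raise CohortFormatError(f"line {lineno}: missing field {key!r}")
    unknown = set(obj) - {"labels", "visits"}
    if unknown:
        raise CohortFormatError(
            f"line {lineno}: unknown field(s) {sorted(unknown)}"
        )
    visits = []
    for j, v in enumerate(obj["visits"]):
        extra = set(v) - {"codes", "labs", "gap_days"}
        if extra:
            raise CohortFormatError(
                f"line {lineno}, visit {j}: unknown field(s) {sorted(extra)}"
            )
        visits.append(Visit(
            codes=set(v.get("codes", [])),
            labs={k: float(x) for k, x in v.get("labs", {}).items()},
            gap_days=v.get("gap_days"),
        ))
    return PatientRecord(labels=set(obj["labels"]), visits=visits)


def read_cohort(path: str | Path) -> list[PatientRecord]:
    """Parse a JSON-lines cohort file, preserving record order.

    Malformed lines raise :class:`CohortFormatError` naming the line
    number; an empty file yields an empty cohort with a warning.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CohortFormatError(f"line {lineno}: invalid JSON ({exc})")
            records.append(_obj_to_record(obj, lineno))
    if not records:
        warnings.warn(f"{path}: empty cohort file")
    return records


def write_cohort(cohort: Sequence[PatientRecord], path: str | Path) -> None:
    """Write a cohort as newline-terminated JSON lines, deterministically."""
    with open(path, "w") as fh:
        for record in cohort:
            fh.write(json.dumps(_record_to_obj(record), sort_keys=True))
            fh.write("\n")


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, network, vocab, bucket_specs=(),
                    extra: dict | None = None) -> None:
    """Single-file checkpoint: parameters + config + vocabulary."""
    meta = {
        "config": network.config.to_dict(),
        "n_codes": network.n_codes,
        "vocab_entries": vocab.entries,
        "vocab_seed": vocab.code_order_seed,
        "vocab_hash": vocab.content_hash(),
        "bucket_specs": [s.to_dict() for s in bucket_specs],
        "extra": extra or {},
    }
    arrays = {f"param::{k}": v for k, v in network.params.items()}
    np.savez_compressed(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path):
    """Inverse of :func:`save_checkpoint`.

    Returns ``(network, vocab, bucket_specs, extra)``.
    """
    from .bucketing import BucketSpec
    from .network import HALOConfig, HALONetwork
    from .vocab import Vocabulary

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        net = HALONetwork(HALOConfig.from_dict(meta["config"]), meta["n_codes"])
        for k in net.params:
            net.params[k] = np.asarray(data[f"param::{k}"], dtype=np.float64)
    vocab = Vocabulary([tuple(e) for e in meta["vocab_entries"]],
                       code_order_seed=meta["vocab_seed"])
    if vocab.content_hash() != meta["vocab_hash"]:
        raise ValueError("vocabulary hash mismatch in checkpoint")
    specs = [BucketSpec.from_dict(d) for d in meta["bucket_specs"]]
    return net, vocab, specs, meta["extra"]
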
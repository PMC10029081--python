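"""Code vocabulary: the ordered universe of binary variables.

The model sees a patient record as a binary matrix whose columns are the
vocabulary positions.  The universe mixes medical codes (diagnoses,
procedures, medications), static label codes (demographics and chronic
phenotypes), bucket codes for discretized continuous variables, and two
special codes marking the start and end of a record.

Medical codes are placed in a seeded random permutation.  Ordering of codes
has no measurable effect on the model, so a reproducible random order is
fixed once and stored with the vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

START_CODE = "<start>"
END_CODE = "<end>"

CATEGORIES = ("medical", "label", "gap_bucket", "lab_bucket", "start", "end")

__all__ = ["Vocabulary", "build_vocabulary", "START_CODE", "END_CODE"]


@dataclass
class Vocabulary:
    """Ordered code universe with category tags and an index map."""

    entries: list[tuple[str, str]]
    code_order_seed: int = 0
    index_of: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.index_of = {code: i for i, (code, _) in enumerate(self.entries)}
        if len(self.index_of) != len(self.entries):
            seen: set[str] = set()
            for code, _ in self.entries:
                if code in seen:
                    raise ValueError(f"duplicate code_id {code!r}")
                seen.add(code)
        for _, cat in self.entries:
            if cat not in CATEGORIES:
                raise ValueError(f"unknown category {cat!r}")
        if len(self.positions_of("start")) != 1 or len(self.positions_of("end")) != 1:
            raise ValueError("vocabulary needs exactly one start and one end code")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, code: str) -> bool:
        return code in self.index_of

    def category(self, code: str) -> str:
        return self.entries[self.index_of[code]][1]

    def positions_of(self, *categories: str) -> np.ndarray:
        """Sorted array of positions whose category is in ``categories``."""
        return np.array(
            [i for i, (_, c) in enumerate(self.entries) if c in categories],
            dtype=np.int64,
        )

    def codes_of(self, *categories: str) -> list[str]:
        return [code for code, c in self.entries if c in categories]

    @property
    def start_index(self) -> int:
        return int(self.positions_of("start")[0])

    @property
    def end_index(self) -> int:
        return int(self.positions_of("end")[0])

    @property
    def label_positions(self) -> np.ndarray:
        return self.positions_of("label")

    @property
    def medical_positions(self) -> np.ndarray:
        return self.positions_of("medical")

    def content_hash(self) -> str:
        """Stable hash of the entry list, used to tie checkpoints to vocabularies."""
        import hashlib

        h = hashlib.sha256()
        for code, cat in self.entries:
            h.update(code.encode())
            h.update(cat.encode())
        return h.hexdigest()[:16]

    # -- serialization: tab-separated code_id, category, index ------------

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#code_order_seed\t{self.code_order_seed}\n")
            for i, (code, cat) in enumerate(self.entries):
                fh.write(f"{code}\t{cat}\t{i}\n")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        entries: list[tuple[str, str]] = []
        seed = 0
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#code_order_seed"):
                    seed = int(line.split("\t")[1])
                    continue
                code, cat, idx = line.split("\t")
                if int(idx) != len(entries):
                    raise ValueError(f"non-contiguous index at {code!r}")
                entries.append((code, cat))
        return cls(entries, code_order_seed=seed)


def build_vocabulary(
    medical_codes: Sequence[str],
    label_codes: Sequence[str] = (),
    bucket_codes: Iterable[tuple[str, str]] = (),
    order_seed: int = 0,
) -> Vocabulary:
    """Assemble a :class:`Vocabulary` from code groups.

    Medical codes are shuffled by a generator seeded with ``order_seed`` so
    the ordering is an explicit, reproducible function of the inputs.  Label
    and bucket codes keep their given order; the start and end codes are
    appended last.

    Raises ``ValueError`` naming the first duplicated code_id.
    """
    bucket_codes = list(bucket_codes)
    all_ids = list(medical_codes) + list(label_codes) + [c for c, _ in bucket_codes]
    seen: set[str] = set()
    for code in all_ids + [START_CODE, END_CODE]:
        if code in seen:
            raise ValueError(f"duplicate code_id {code!r}")
        seen.add(code)

    rng = np.random.default_rng(order_seed)
    order = rng.permutation(len(medical_codes))
    entries: list[tuple[str, str]] = [(medical_codes[i], "medical") for i in order]
    entries += [(c, "label") for c in label_codes]
    for code, cat in bucket_codes:
        if cat not in ("gap_bucket", "lab_bucket"):
            raise ValueError(f"bucket code {code!r} has category {cat!r}")
        entries.append((code, cat))
    entries.append((START_CODE, "start"))
    entries.append((END_CODE, "end"))
    return Vocabulary(entries, code_order_seed=order_seed)
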
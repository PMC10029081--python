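"""Privacy audit: membership inference, attribute inference, NNAA risk.

All distance-based attacks operate on record *fingerprints*: fixed-length
binary vectors over the vocabulary marking the presence of each code
anywhere in a record (label row plus every visit; start/end codes excluded).
Distances are Hamming distances between fingerprints, computed exactly via
the identity  ``d(a, b) = |a| + |b| - 2 a.b``  for binary vectors.

* Membership inference labels the half of an equal-sized member/non-member
  attack set with the best score (lowest distance to the synthetic cohort,
  or highest model log-likelihood) as members and reports
  accuracy/precision/recall against the truth.
* Attribute inference finds, for each target record, the reference record
  agreeing most on the *conditional* attributes (labels plus the most
  common medical codes) and predicts the remaining *sensitive* medical
  codes verbatim, scored by micro-F1.
* Nearest Neighbor Adversarial Accuracy (NNAA) compares, between dataset
  pairs, how often a record's nearest neighbor lies in its own dataset;
  risk is the training-vs-evaluation asymmetry ``aa_es - aa_ts`` and is
  near 0 when the generator is not copying its training data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .bucketing import BucketSpec
from .fidelity import visit_code_sets
from .network import HALONetwork
from .records import PatientRecord, encode_cohort
from .vocab import Vocabulary

__all__ = [
    "fingerprint",
    "fingerprints",
    "hamming",
    "membership_dataset_attack",
    "membership_model_attack",
    "attribute_inference_attack",
    "nnaa",
    "PrivacyReport",
]


def fingerprint(record: PatientRecord, vocab: Vocabulary,
                bucket_specs: Sequence[BucketSpec] = ()) -> np.ndarray:
    """Binary presence vector of length ``|C|``: bit ``c`` is 1 iff code
    ``c`` occurs in the record's labels or any visit."""
    bits = np.zeros(len(vocab), dtype=np.uint8)
    for code in record.labels:
        bits[vocab.index_of[code]] = 1
    for codes in visit_code_sets(record, bucket_specs):
        for code in codes:
            bits[vocab.index_of[code]] = 1
    return bits


def fingerprints(cohort: Sequence[PatientRecord], vocab: Vocabulary,
                 bucket_specs: Sequence[BucketSpec] = ()) -> np.ndarray:
    return np.stack([fingerprint(r, vocab, bucket_specs) for r in cohort])


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    """Number of differing bits between two equal-length binary vectors."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return int(np.sum(a != b))


def _pairwise_hamming(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """(|A|, |B|) matrix of Hamming distances between binary row vectors."""
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    d = A.sum(1)[:, None] + B.sum(1)[None, :] - 2.0 * (A @ B.T)
    return np.rint(d)


def _as_fps(x, vocab, bucket_specs):
    if isinstance(x, np.ndarray):
        return x
    return fingerprints(x, vocab, bucket_specs)


def _rank_metrics(scores: np.ndarray, truth: np.ndarray,
                  n_positive: int) -> dict[str, float]:
    """Label the ``n_positive`` best-scoring records (lowest score) as
    members; ties are broken by stable record order."""
    order = np.argsort(scores, kind="stable")
    pred = np.zeros(scores.size, dtype=bool)
    pred[order[:n_positive]] = True
    tp = np.sum(pred & truth)
    fp = np.sum(pred & ~truth)
    fn = np.sum(~pred & truth)
    acc = np.mean(pred == truth)
    return {
        "accuracy": float(acc),
        "precision": float(tp / (tp + fp)) if tp + fp else 0.0,
        "recall": float(tp / (tp + fn)) if tp + fn else 0.0,
    }


def membership_dataset_attack(
    synthetic, members, nonmembers,
    vocab: Vocabulary | None = None,
    bucket_specs: Sequence[BucketSpec] = (),
) -> dict[str, float]:
    """Hamming-distance membership inference against the synthetic cohort.

    Each attack record is scored by its minimum fingerprint distance to any
    synthetic record; the half with the lowest distances is labeled as
    training members.  Arguments may be cohorts (with ``vocab``) or
    precomputed fingerprint matrices.
    """
    S = _as_fps(synthetic, vocab, bucket_specs)
    M = _as_fps(members, vocab, bucket_specs)
    NM = _as_fps(nonmembers, vocab, bucket_specs)
    if len(S) == 0:
        raise ValueError("empty synthetic cohort")
    if len(M) != len(NM) or len(M) == 0:
        raise ValueError("need equal, non-empty member and non-member sets")
    attack = np.concatenate([M, NM])
    scores = _pairwise_hamming(attack, S).min(axis=1)
    truth = np.zeros(len(attack), dtype=bool)
    truth[: len(M)] = True
    return _rank_metrics(scores, truth, len(M))


def membership_model_attack(
    net: HALONetwork,
    members: Sequence[PatientRecord],
    nonmembers: Sequence[PatientRecord],
    vocab: Vocabulary,
    bucket_specs: Sequence[BucketSpec] = (),
    max_T: int | None = None,
) -> dict[str, float]:
    """Model-based membership inference: score records by log-likelihood
    and label the top half as members.

    Raw log-probabilities are used without length normalization, so longer
    records score systematically lower; that confound is part of the attack
    as specified.
    """
    if len(members) != len(nonmembers) or len(members) == 0:
        raise ValueError("need equal, non-empty member and non-member sets")
    if max_T is None:
        max_T = net.config.max_T
    cohort = list(members) + list(nonmembers)
    R, valid = encode_cohort(cohort, vocab, bucket_specs, max_T=max_T, clamp=True)
    ll = net.log_likelihoods(R, valid)
    truth = np.zeros(len(cohort), dtype=bool)
    truth[: len(members)] = True
    # highest likelihood first -> negate so "lowest score" = member
    return _rank_metrics(-ll, truth, len(members))


def attribute_inference_attack(
    reference, target,
    vocab: Vocabulary,
    k_common: int = 500,
    bucket_specs: Sequence[BucketSpec] = (),
) -> float:
    """Nearest-neighbor attribute inference; returns micro-averaged F1.

    Conditional attributes are the label codes plus the ``k_common`` most
    prevalent medical codes (prevalence measured on the target cohort,
    which plays the training-data role).  For each target record the
    reference record with the smallest Hamming distance on the conditional
    sub-vector (ties: lowest index) donates its sensitive bits verbatim.
    """
    ref = _as_fps(reference, vocab, bucket_specs)
    tgt = _as_fps(target, vocab, bucket_specs)
    if len(ref) == 0 or len(tgt) == 0:
        raise ValueError("empty cohort")
    med = vocab.medical_positions
    if k_common >= med.size:
        raise ValueError(f"k_common={k_common} must be < {med.size} medical codes")
    prevalence = tgt[:, med].mean(axis=0)
    order = np.argsort(-prevalence, kind="stable")
    common_med = med[order[:k_common]]
    sensitive = np.sort(med[order[k_common:]])
    conditional = np.sort(np.concatenate([vocab.label_positions, common_med]))

    d = _pairwise_hamming(tgt[:, conditional], ref[:, conditional])
    nearest = d.argmin(axis=1)  # argmin takes the lowest index on ties
    pred = ref[nearest][:, sensitive]
    true = tgt[:, sensitive]
    tp = np.sum((pred == 1) & (true == 1))
    fp = np.sum((pred == 1) & (true == 0))
    fn = np.sum((pred == 0) & (true == 1))
    return float(2 * tp / (2 * tp + fp + fn)) if (2 * tp + fp + fn) else 0.0


def _min_dists(A: np.ndarray, B: np.ndarray, exclude_self: bool) -> np.ndarray:
    d = _pairwise_hamming(A, B)
    if exclude_self:
        np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def nnaa(
    train, synthetic, evaluation,
    n: int,
    rng: np.random.Generator,
    vocab: Vocabulary | None = None,
    bucket_specs: Sequence[BucketSpec] = (),
) -> dict[str, float]:
    """Nearest Neighbor Adversarial Accuracy risk.

    Draws subsets of size ``n`` from the training, synthetic and evaluation
    cohorts, then computes the four indicator means with strict ``>`` and
    self-exclusion for within-set nearest neighbors:

        aa_es = (P[d_ES > d_EE] + P[d_SE > d_SS]) / 2
        aa_ts = (P[d_TS > d_TT] + P[d_ST > d_SS]) / 2
        risk  = aa_es - aa_ts
    """
    T = _as_fps(train, vocab, bucket_specs)
    S = _as_fps(synthetic, vocab, bucket_specs)
    E = _as_fps(evaluation, vocab, bucket_specs)
    for name, X in (("train", T), ("synthetic", S), ("evaluation", E)):
        if len(X) < n:
            raise ValueError(f"{name} cohort smaller than n={n}")
    St = T[rng.choice(len(T), n, replace=False)]
    Ss = S[rng.choice(len(S), n, replace=False)]
    Se = E[rng.choice(len(E), n, replace=False)]

    d_es = _min_dists(Se, Ss, exclude_self=False)
    d_ee = _min_dists(Se, Se, exclude_self=True)
    d_se = _min_dists(Ss, Se, exclude_self=False)
    d_ss = _min_dists(Ss, Ss, exclude_self=True)
    d_ts = _min_dists(St, Ss, exclude_self=False)
    d_tt = _min_dists(St, St, exclude_self=True)
    d_st = _min_dists(Ss, St, exclude_self=False)

    aa_es = 0.5 * (np.mean(d_es > d_ee) + np.mean(d_se > d_ss))
    aa_ts = 0.5 * (np.mean(d_ts > d_tt) + np.mean(d_st > d_ss))
    return {"aa_es": float(aa_es), "aa_ts": float(aa_ts),
            "risk": float(aa_es - aa_ts)}


@dataclass
class PrivacyReport:
    """Bundle of all three privacy evaluations."""

    membership_dataset: dict[str, float]
    membership_model: dict[str, float] | None
    attribute_f1: float
    nnaa: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "membership_dataset": self.membership_dataset,
            "membership_model": self.membership_model,
            "attribute_f1": self.attribute_f1,
            "nnaa": self.nnaa,
        }
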
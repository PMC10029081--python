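"""Fidelity battery: code-prediction metrics, perplexity, probability
profiles with R-squared, and aggregate cohort statistics.

The statistical-similarity comparison works on *probability profiles*:
unigram (single code), same-visit bigram (unordered pair within a visit)
and sequential bigram (ordered pair in consecutive visits) probabilities,
normalized either per record or per visit.  Profiles of a real and a
synthetic cohort are compared by the squared Pearson correlation of the
aligned probability vectors over the union of observed keys (a key absent
from one profile contributes probability zero).

Perplexity per code is ``exp(-sum_R log P(R) / N)`` where ``N`` counts the
present (1) code bits over valid non-start rows in the cohort — the number
of codes the likelihood is normalized by.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .bucketing import BucketSpec, bucket_index
from .network import HALONetwork, masked_bce_loss
from .records import GAP_VARIABLE, PatientRecord

__all__ = [
    "ProbabilityProfile",
    "FidelityReport",
    "probability_profile",
    "r_squared",
    "code_prediction_metrics",
    "perplexity_per_code",
    "aggregate_stats",
    "fidelity_report",
]


@dataclass
class ProbabilityProfile:
    """Unigram / bigram probability maps at one normalization level."""

    level: str  # "record" or "visit"
    unigram: dict[str, float]
    same_visit_bigram: dict[frozenset, float]
    sequential_bigram: dict[tuple, float]
    denominators: dict[str, int]


def visit_code_sets(record: PatientRecord,
                    bucket_specs: Sequence[BucketSpec] = ()) -> list[set[str]]:
    """Per-visit code sets counted by the profiles: medical codes plus the
    bucket codes of any labs/gaps (labels and specials excluded)."""
    specs = {s.variable_id: s for s in bucket_specs}
    out = []
    for t, v in enumerate(record.visits):
        codes = set(v.codes)
        for lab_id, value in v.labs.items():
            if lab_id in specs:
                s = specs[lab_id]
                codes.add(s.code_ids[bucket_index(float(value), s, clamp=True)])
        if t >= 1 and v.gap_days is not None and GAP_VARIABLE in specs:
            s = specs[GAP_VARIABLE]
            codes.add(s.code_ids[bucket_index(float(v.gap_days), s, clamp=True)])
        out.append(codes)
    return out


def probability_profile(
    cohort: Sequence[PatientRecord],
    level: str = "record",
    bucket_specs: Sequence[BucketSpec] = (),
) -> ProbabilityProfile:
    """Empirical unigram/bigram probabilities of a cohort.

    At record level every map's denominator is the number of records and a
    record counts once per key no matter how often the pattern recurs; at
    visit level the denominators are visits (unigram, same-visit) and
    consecutive-visit transitions (sequential).
    """
    if level not in ("record", "visit"):
        raise ValueError(f"level must be 'record' or 'visit', got {level!r}")
    if len(cohort) == 0:
        raise ValueError("empty cohort")

    uni: dict[str, int] = {}
    same: dict[frozenset, int] = {}
    seq: dict[tuple, int] = {}
    n_visits = 0
    n_transitions = 0

    for record in cohort:
        sets = visit_code_sets(record, bucket_specs)
        n_visits += len(sets)
        n_transitions += max(len(sets) - 1, 0)
        if level == "record":
            u_keys: set[str] = set()
            s_keys: set[frozenset] = set()
            q_keys: set[tuple] = set()
            for codes in sets:
                u_keys |= codes
                for a, b in itertools.combinations(sorted(codes), 2):
                    s_keys.add(frozenset((a, b)))
            for prev, nxt in zip(sets, sets[1:]):
                for a in prev:
                    for b in nxt:
                        q_keys.add((a, b))
            for k in u_keys:
                uni[k] = uni.get(k, 0) + 1
            for k in s_keys:
                same[k] = same.get(k, 0) + 1
            for k in q_keys:
                seq[k] = seq.get(k, 0) + 1
        else:
            for codes in sets:
                for k in codes:
                    uni[k] = uni.get(k, 0) + 1
                for a, b in itertools.combinations(sorted(codes), 2):
                    key = frozenset((a, b))
                    same[key] = same.get(key, 0) + 1
            for prev, nxt in zip(sets, sets[1:]):
                for a in prev:
                    for b in nxt:
                        seq[(a, b)] = seq.get((a, b), 0) + 1

    if level == "record":
        d_uni = d_same = d_seq = len(cohort)
    else:
        d_uni = d_same = max(n_visits, 1)
        d_seq = max(n_transitions, 1)
    return ProbabilityProfile(
        level=level,
        unigram={k: v / d_uni for k, v in uni.items()},
        same_visit_bigram={k: v / d_same for k, v in same.items()},
        sequential_bigram={k: v / d_seq for k, v in seq.items()},
        denominators={"unigram": d_uni, "same_visit": d_same,
                      "sequential": d_seq},
    )


def _component_map(profile: ProbabilityProfile, component: str) -> dict:
    try:
        return {"unigram": profile.unigram,
                "same_visit": profile.same_visit_bigram,
                "sequential": profile.sequential_bigram}[component]
    except KeyError:
        raise ValueError(f"unknown component {component!r}") from None


def r_squared(profile_a: ProbabilityProfile, profile_b: ProbabilityProfile,
              component: str = "unigram") -> float:
    """Squared Pearson correlation between two aligned probability maps.

    Keys are the union of the two profiles; a missing key contributes 0.
    Degenerate inputs (fewer than two keys, or zero variance on either
    side) return 0 with a warning.  Note this measures correlation, not
    ``y = x`` agreement.
    """
    if profile_a.level != profile_b.level:
        raise ValueError("profiles have different normalization levels")
    ma, mb = _component_map(profile_a, component), _component_map(profile_b, component)
    keys = sorted(set(ma) | set(mb), key=repr)
    if len(keys) < 2:
        warnings.warn("fewer than two keys; R^2 undefined, returning 0")
        return 0.0
    xa = np.array([ma.get(k, 0.0) for k in keys])
    xb = np.array([mb.get(k, 0.0) for k in keys])
    if np.std(xa) == 0 or np.std(xb) == 0:
        warnings.warn("zero-variance profile; R^2 undefined, returning 0")
        return 0.0
    r = np.corrcoef(xa, xb)[0, 1]
    return float(r * r)


def code_prediction_metrics(
    net: HALONetwork,
    R: np.ndarray,
    valid: np.ndarray,
    threshold: float = 0.5,
    chunk: int = 256,
) -> dict[str, float]:
    """Masked BCE and micro-averaged F1 of thresholded code predictions.

    Positions counted are all codes of valid non-start rows; the prediction
    for a position is ``O >= threshold`` against the true bit.
    """
    R = np.asarray(R, dtype=np.float64)
    valid = np.asarray(valid, dtype=np.float64)
    if R.shape[0] == 0:
        raise ValueError("empty cohort")
    tp = fp = fn = 0.0
    bce_num = 0.0
    n_rows = 0.0
    for lo in range(0, R.shape[0], chunk):
        hi = lo + chunk
        O = net.forward(R[lo:hi])
        t = R[lo:hi, 1:, :]
        m = valid[lo:hi, 1:]
        bce_num += masked_bce_loss(O, t, m, eps=net.config.prob_floor) \
            * m.sum() * net.n_codes
        n_rows += m.sum()
        pred = (O >= threshold) & (m[:, :, None] > 0)
        true = (t > 0) & (m[:, :, None] > 0)
        tp += np.sum(pred & true)
        fp += np.sum(pred & ~true)
        fn += np.sum(~pred & true)
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    return {"bce": bce_num / (n_rows * net.n_codes), "f1": float(f1)}


def count_present_codes(R: np.ndarray, valid: np.ndarray,
                        visit_rows_only: bool = False) -> int:
    """Total 1-bits over valid non-start rows — perplexity's normalizer.

    With ``visit_rows_only`` the label and end rows are excluded and only
    clinical visit rows (indices 2..T+1) are counted; the default includes
    every row the likelihood itself covers.
    """
    R = np.asarray(R, dtype=np.float64)
    valid = np.asarray(valid, dtype=np.float64)
    if visit_rows_only:
        v = valid.copy()
        v[:, :2] = 0  # start + label rows
        for i, n_valid in enumerate(valid.sum(axis=1).astype(int)):
            v[i, n_valid - 1] = 0  # end row
        return int((R * v[:, :, None]).sum())
    return int((R[:, 1:, :] * valid[:, 1:, None]).sum())


def perplexity_per_code(net: HALONetwork, R: np.ndarray,
                        valid: np.ndarray,
                        visit_rows_only: bool = False) -> float:
    """Per-present-code perplexity of a cohort under the network."""
    N = count_present_codes(R, valid, visit_rows_only=visit_rows_only)
    if N == 0:
        raise ValueError("cohort contains no present codes")
    ll = net.log_likelihoods(R, valid)
    return float(np.exp(-ll.sum() / N))


def aggregate_stats(cohort: Sequence[PatientRecord]) -> dict:
    """Record-length and visit-length moments plus label prevalences.

    Visit length counts medical codes only.  Standard deviations use the
    population convention (ddof=0).
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    rec_lens = np.array([r.n_visits for r in cohort], dtype=float)
    visit_lens = np.array(
        [len(v.codes) for r in cohort for v in r.visits], dtype=float
    )
    labels: dict[str, int] = {}
    for r in cohort:
        for code in r.labels:
            labels[code] = labels.get(code, 0) + 1
    return {
        "record_length_mean": float(rec_lens.mean()),
        "record_length_sd": float(rec_lens.std()),
        "visit_length_mean": float(visit_lens.mean()) if visit_lens.size else 0.0,
        "visit_length_sd": float(visit_lens.std()) if visit_lens.size else 0.0,
        "label_prevalence": {k: v / len(cohort) for k, v in sorted(labels.items())},
    }


@dataclass
class FidelityReport:
    """Everything the fidelity battery computes, in one place."""

    bce: float | None
    f1: float | None
    perplexity_per_code: float | None
    r2_unigram: float
    r2_same_visit: float
    r2_sequential: float
    aggregate_real: dict = field(default_factory=dict)
    aggregate_synthetic: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "bce": self.bce, "f1": self.f1,
            "perplexity_per_code": self.perplexity_per_code,
            "r2_unigram": self.r2_unigram,
            "r2_same_visit": self.r2_same_visit,
            "r2_sequential": self.r2_sequential,
            "aggregate_real": self.aggregate_real,
            "aggregate_synthetic": self.aggregate_synthetic,
        }


def fidelity_report(
    real: Sequence[PatientRecord],
    synthetic: Sequence[PatientRecord],
    level: str = "record",
    bucket_specs: Sequence[BucketSpec] = (),
    net: HALONetwork | None = None,
    encoded: tuple[np.ndarray, np.ndarray] | None = None,
) -> FidelityReport:
    """Full statistical-similarity report between two cohorts.

    If ``net`` and the encoded real cohort are supplied, the model-based
    metrics (BCE, F1, perplexity) are included as well.
    """
    pr = probability_profile(real, level, bucket_specs)
    ps = probability_profile(synthetic, level, bucket_specs)
    bce = f1 = pp = None
    if net is not None and encoded is not None:
        m = code_prediction_metrics(net, *encoded)
        bce, f1 = m["bce"], m["f1"]
        pp = perplexity_per_code(net, *encoded)
    return FidelityReport(
        bce=bce, f1=f1, perplexity_per_code=pp,
        r2_unigram=r_squared(pr, ps, "unigram"),
        r2_same_visit=r_squared(pr, ps, "same_visit"),
        r2_sequential=r_squared(pr, ps, "sequential"),
        aggregate_real=aggregate_stats(real),
        aggregate_synthetic=aggregate_stats(synthetic),
    )
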
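"""Ground-truth cohort simulator.

Real claims / ICU corpora are proprietary or credentialed, so the package
ships a configurable generative process that reproduces the *structural*
features the generator must learn, without any claim of clinical realism:

* label-dependent code prevalence — condition "modules" (think disease
  processes) activate when a patient carries their trigger labels and emit
  their member codes;
* within-visit co-occurrence — an active module emits several of its codes
  in the same visit;
* cross-visit persistence — once a module code has appeared it recurs in
  later visits with a persistence probability (chronic repetition);
* heavy-tailed record lengths — visit counts follow a negative binomial
  truncated to ``[1, max_T]``;
* log-normal visit gaps whose location drifts down with visit index
  (long records end up with shorter gaps);
* label-shifted lab values — normal labs whose mean moves with labels.

The process exposes oracle probabilities (closed form where available,
Monte Carlo otherwise) through an *independent* sampler implementation so
the main sampler can be cross-checked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .bucketing import BucketSpec
from .fidelity import ProbabilityProfile, probability_profile
from .records import GAP_VARIABLE, PatientRecord, Visit
from .vocab import Vocabulary, build_vocabulary

__all__ = [
    "ConditionModule",
    "LabModel",
    "GroundTruthProcess",
    "make_process",
    "sample_cohort_sim",
    "oracle_profile",
]


@dataclass(frozen=True)
class ConditionModule:
    """A block of codes that co-occur and persist when triggered by labels.

    ``emission`` is the per-visit probability of each member code while the
    module is active; once a code has appeared it recurs in every later
    visit with probability ``persistence`` instead.
    """

    trigger_labels: tuple[str, ...]
    codes: tuple[str, ...]
    emission: tuple[float, ...]
    persistence: float

    def __post_init__(self) -> None:
        if len(self.codes) != len(self.emission):
            raise ValueError("one emission probability per module code")
        for p in (*self.emission, self.persistence):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")


@dataclass(frozen=True)
class LabModel:
    """Normal lab with label-dependent mean shift, truncated to [lo, hi]."""

    presence: float
    mean: float
    sd: float
    shifts: tuple[tuple[str, float], ...] = ()
    lo: float = -np.inf
    hi: float = np.inf

    def value_params(self, labels: frozenset[str]) -> tuple[float, float]:
        mu = self.mean + sum(delta for lab, delta in self.shifts if lab in labels)
        return mu, self.sd


@dataclass
class GroundTruthProcess:
    """Fully specified generative process for synthetic ground truth."""

    label_prevalences: dict[str, float]
    medical_codes: tuple[str, ...]
    modules: tuple[ConditionModule, ...]
    background_rates: dict[str, float]
    visit_count_r: float
    visit_count_p: float
    max_T: int
    gap_mu: float
    gap_sigma: float
    gap_slope: float
    gap_max: float
    labs: dict[str, LabModel]
    seed: int = 0
    gap_bounds: tuple[float, ...] = ()
    lab_bounds: dict[str, tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for p in self.label_prevalences.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"label prevalence {p} outside [0, 1]")
        for c, p in self.background_rates.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"background rate {p} for {c} outside [0, 1]")
        if self.gap_sigma <= 0:
            raise ValueError("gap_sigma must be positive")
        if self.max_T < 1:
            raise ValueError("max_T must be >= 1")

    # -- derived artifacts -------------------------------------------------

    def bucket_specs(self) -> list[BucketSpec]:
        specs = []
        if self.gap_bounds:
            specs.append(
                BucketSpec(GAP_VARIABLE, self.gap_bounds, "explicit").with_codes(
                    tuple(f"{GAP_VARIABLE}:bucket{k}"
                          for k in range(len(self.gap_bounds) - 1))
                )
            )
        for lab_id, bounds in self.lab_bounds.items():
            specs.append(
                BucketSpec(lab_id, bounds, "explicit").with_codes(
                    tuple(f"{lab_id}:bucket{k}" for k in range(len(bounds) - 1))
                )
            )
        return specs

    def vocabulary(self, order_seed: int | None = None) -> Vocabulary:
        bucket_codes = []
        for spec in self.bucket_specs():
            cat = "gap_bucket" if spec.variable_id == GAP_VARIABLE else "lab_bucket"
            bucket_codes += [(c, cat) for c in spec.code_ids]
        return build_vocabulary(
            list(self.medical_codes),
            sorted(self.label_prevalences),
            bucket_codes,
            order_seed=self.seed if order_seed is None else order_seed,
        )

    def truncated_visit_count_mean(self) -> float:
        """Analytic mean of the visit-count distribution after truncation."""
        ks = np.arange(1, self.max_T + 1)
        pmf = stats.nbinom.pmf(ks, self.visit_count_r, self.visit_count_p)
        return float((ks * pmf).sum() / pmf.sum())

    def _gap_mu_at(self, t: int) -> float:
        return self.gap_mu - self.gap_slope * np.log1p(t)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "label_prevalences": dict(self.label_prevalences),
            "medical_codes": list(self.medical_codes),
            "modules": [
                {"trigger_labels": list(m.trigger_labels), "codes": list(m.codes),
                 "emission": list(m.emission), "persistence": m.persistence}
                for m in self.modules
            ],
            "background_rates": dict(self.background_rates),
            "visit_count_r": self.visit_count_r,
            "visit_count_p": self.visit_count_p,
            "max_T": self.max_T,
            "gap_mu": self.gap_mu, "gap_sigma": self.gap_sigma,
            "gap_slope": self.gap_slope, "gap_max": self.gap_max,
            "labs": {
                k: {"presence": v.presence, "mean": v.mean, "sd": v.sd,
                    "shifts": [list(s) for s in v.shifts],
                    "lo": v.lo, "hi": v.hi}
                for k, v in self.labs.items()
            },
            "seed": self.seed,
            "gap_bounds": list(self.gap_bounds),
            "lab_bounds": {k: list(v) for k, v in self.lab_bounds.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthProcess":
        return cls(
            label_prevalences=dict(d["label_prevalences"]),
            medical_codes=tuple(d["medical_codes"]),
            modules=tuple(
                ConditionModule(tuple(m["trigger_labels"]), tuple(m["codes"]),
                                tuple(m["emission"]), m["persistence"])
                for m in d["modules"]
            ),
            background_rates=dict(d["background_rates"]),
            visit_count_r=d["visit_count_r"], visit_count_p=d["visit_count_p"],
            max_T=d["max_T"], gap_mu=d["gap_mu"], gap_sigma=d["gap_sigma"],
            gap_slope=d["gap_slope"], gap_max=d["gap_max"],
            labs={
                k: LabModel(v["presence"], v["mean"], v["sd"],
                            tuple((s[0], s[1]) for s in v["shifts"]),
                            v["lo"], v["hi"])
                for k, v in d["labs"].items()
            },
            seed=d.get("seed", 0),
            gap_bounds=tuple(d.get("gap_bounds", ())),
            lab_bounds={k: tuple(v) for k, v in d.get("lab_bounds", {}).items()},
        )


def make_process(config: str | dict = "small", seed: int = 0) -> GroundTruthProcess:
    """Build a :class:`GroundTruthProcess` from a preset name or a config dict.

    The ``"small"`` preset: 120 medical codes, 4 labels, 6 condition
    modules, visits truncated to at most 12, one gap variable and two labs.
    Construction is deterministic in ``seed`` (which also drives the
    heavy-tailed background-rate draw).
    """
    if isinstance(config, dict):
        d = dict(config)
        d.setdefault("seed", seed)
        return GroundTruthProcess.from_dict(d)
    if config != "small":
        raise ValueError(f"unknown preset {config!r}")

    rng = np.random.default_rng(seed)
    n_codes = 120
    codes = tuple(f"C{i:03d}" for i in range(n_codes))
    labels = ["L0", "L1", "L2", "L3"]
    prevalences = {"L0": 0.35, "L1": 0.25, "L2": 0.15, "L3": 0.08}

    emission = (0.45, 0.35, 0.28, 0.22, 0.18, 0.14, 0.11, 0.09, 0.07, 0.05)
    triggers = [("L0",), ("L1",), ("L2",), ("L3",), ("L0", "L1"), ()]
    modules = tuple(
        ConditionModule(
            trigger_labels=triggers[m],
            codes=codes[10 * m: 10 * (m + 1)],
            emission=emission if m < 5 else tuple(e * 0.5 for e in emission),
            persistence=0.65,
        )
        for m in range(6)
    )
    # heavy-tailed per-visit background rates for every code
    background = {
        c: float(10.0 ** rng.uniform(-2.8, -1.4)) for c in codes
    }

    labs = {
        "lab_hr": LabModel(presence=0.30, mean=80.0, sd=12.0,
                           shifts=(("L1", 8.0),), lo=30.0, hi=199.9),
        "lab_glucose": LabModel(presence=0.25, mean=100.0, sd=20.0,
                                shifts=(("L0", 15.0),), lo=40.0, hi=299.9),
    }
    return GroundTruthProcess(
        label_prevalences=prevalences,
        medical_codes=codes,
        modules=modules,
        background_rates=background,
        visit_count_r=2.0,
        visit_count_p=0.35,
        max_T=12,
        gap_mu=3.2,
        gap_sigma=0.7,
        gap_slope=0.25,
        gap_max=999.0,
        labs=labs,
        seed=seed,
        gap_bounds=(0.0, 3.0, 7.0, 14.0, 30.0, 60.0, 120.0, 1000.0),
        lab_bounds={
            "lab_hr": (30.0, 60.0, 70.0, 80.0, 90.0, 100.0, 120.0, 200.0),
            "lab_glucose": (40.0, 70.0, 85.0, 100.0, 115.0, 130.0, 160.0, 300.0),
        },
    )


def _draw_visit_count(process: GroundTruthProcess,
                      rng: np.random.Generator) -> int:
    while True:
        t = int(rng.negative_binomial(process.visit_count_r,
                                      process.visit_count_p))
        if 1 <= t <= process.max_T:
            return t


def sample_cohort_sim(process: GroundTruthProcess, n: int,
                      seed: int = 0) -> list[PatientRecord]:
    """Draw ``n`` patient records from the process; reproducible per seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    code_list = list(process.medical_codes)
    bg = np.array([process.background_rates[c] for c in code_list])
    records = []
    for _ in range(n):
        labels = frozenset(
            lab for lab, p in process.label_prevalences.items()
            if rng.random() < p
        )
        T = _draw_visit_count(process, rng)
        active = [m for m in process.modules
                  if set(m.trigger_labels) <= labels]
        started: set[str] = set()
        visits = []
        for t in range(T):
            codes = set(np.array(code_list)[rng.random(len(code_list)) < bg])
            for mod in active:
                for code, em in zip(mod.codes, mod.emission):
                    p = mod.persistence if code in started else em
                    if rng.random() < p:
                        codes.add(code)
            started |= codes  # persistence triggers on any appearance
            labs = {}
            for lab_id, lm in process.labs.items():
                if rng.random() < lm.presence:
                    mu, sd = lm.value_params(labels)
                    labs[lab_id] = float(np.clip(rng.normal(mu, sd), lm.lo, lm.hi))
            gap = None
            if t >= 1:
                gap = float(min(rng.lognormal(process._gap_mu_at(t),
                                              process.gap_sigma),
                                process.gap_max))
            visits.append(Visit(codes=codes, labs=labs, gap_days=gap))
        records.append(PatientRecord(labels=set(labels), visits=visits))
    return records


# ---------------------------------------------------------------------------
# oracle: independent sampler + closed forms
# ---------------------------------------------------------------------------

def _oracle_sample_record(process: GroundTruthProcess,
                          rng: np.random.Generator) -> PatientRecord:
    """Independent re-implementation of the generative process.

    Written as an explicit per-visit probability-vector construction (one
    Bernoulli vector draw per visit) rather than per-code loops, so it
    shares no code path with :func:`sample_cohort_sim`.
    """
    code_list = list(process.medical_codes)
    index = {c: i for i, c in enumerate(code_list)}
    labels = frozenset(
        lab for lab, prob in process.label_prevalences.items()
        if rng.random() < prob
    )
    # truncated negative binomial via inverse-cdf on the renormalized pmf
    ks = np.arange(1, process.max_T + 1)
    pmf = stats.nbinom.pmf(ks, process.visit_count_r, process.visit_count_p)
    cdf = np.cumsum(pmf / pmf.sum())
    T = int(ks[np.searchsorted(cdf, rng.random())])

    base = np.array([process.background_rates[c] for c in code_list])
    module_rows = []
    for mod in process.modules:
        if set(mod.trigger_labels) <= labels:
            row = np.zeros(len(code_list))
            row[[index[c] for c in mod.codes]] = mod.emission
            module_rows.append((row, np.array([index[c] for c in mod.codes]),
                                mod.persistence))
    started = np.zeros(len(code_list), dtype=bool)
    visits = []
    for t in range(T):
        # background and module emissions combine as independent causes
        pvec = base.copy()
        for row, pos, pers in module_rows:
            mod_p = np.where(started[pos], pers, row[pos])
            pvec[pos] = 1.0 - (1.0 - base[pos]) * (1.0 - mod_p)
        draws = rng.random(len(code_list)) < pvec
        started |= draws
        codes = {code_list[i] for i in np.flatnonzero(draws)}
        labs = {}
        for lab_id, lm in process.labs.items():
            if rng.random() < lm.presence:
                mu, sd = lm.value_params(labels)
                labs[lab_id] = float(np.clip(rng.normal(mu, sd), lm.lo, lm.hi))
        gap = None
        if t >= 1:
            gap = float(min(rng.lognormal(process._gap_mu_at(t),
                                          process.gap_sigma), process.gap_max))
        visits.append(Visit(codes=codes, labs=labs, gap_days=gap))
    return PatientRecord(labels=set(labels), visits=visits)


def oracle_profile(process: GroundTruthProcess, level: str = "record",
                   n_mc: int = 5000, seed: int = 0) -> ProbabilityProfile:
    """Monte-Carlo estimate of the process's true probability profile,
    using the independent sampler as a cross-check code path."""
    if n_mc < 1000:
        raise ValueError("n_mc must be >= 1000 for a stable estimate")
    rng = np.random.default_rng(seed)
    cohort = [_oracle_sample_record(process, rng) for _ in range(n_mc)]
    return probability_profile(cohort, level, process.bucket_specs())


def closed_form_visit_unigram(process: GroundTruthProcess) -> dict[str, float]:
    """Exact per-visit unigram probabilities for a module-free process."""
    if process.modules:
        raise ValueError("closed form only available without modules")
    return dict(process.background_rates)
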
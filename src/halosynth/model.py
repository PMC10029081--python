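"""Model / Results surface.

:class:`HALO` is constructed from a cohort and a vocabulary (the data and
its code universe); :meth:`HALO.fit` trains the two-level autoregressive
network and returns a :class:`HALOResults` carrying the trained parameters,
the loss trace, and diagnostics.  Generation, likelihood evaluation,
fidelity metrics and the privacy audit all hang off the results object.

Example
-------
>>> from halosynth import simulate, HALO
>>> process = simulate.make_process("small", seed=7)
>>> cohort = simulate.sample_cohort_sim(process, 500, seed=8)
>>> model = HALO(cohort, process.vocabulary(), process.bucket_specs(),
...              M=2, n_emb=64, n_heads=4, max_T=12)
>>> res = model.fit(epochs=5, seed=0)
>>> synthetic = res.sample_cohort(500, seed=1)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import fidelity as _fidelity
from .bucketing import BucketSpec
from .io import load_checkpoint, save_checkpoint
from .network import HALOConfig, HALONetwork, train_network
from .records import PatientRecord, RecordMatrix, encode_cohort, encode_record
from .sampling import GenerationSpec, sample_cohort, sample_matrices
from .vocab import Vocabulary

__all__ = ["HALO", "HALOResults"]


class HALO:
    """Hierarchical autoregressive generator over a fixed cohort.

    Parameters
    ----------
    cohort
        Training records; every code must resolve in ``vocab`` and no
        record may exceed ``max_T`` visits.
    vocab
        The code universe.
    bucket_specs
        Bucketing schemes for continuous variables present in the cohort.
    config
        A full :class:`HALOConfig`; alternatively pass individual fields
        as keyword arguments (``M=2, n_emb=64, ...``).
    """

    def __init__(
        self,
        cohort: Sequence[PatientRecord],
        vocab: Vocabulary,
        bucket_specs: Sequence[BucketSpec] = (),
        config: HALOConfig | None = None,
        **config_kwargs,
    ):
        if config is None:
            config = HALOConfig(**config_kwargs)
        elif config_kwargs:
            raise TypeError("pass either config or keyword fields, not both")
        self.config = config
        self.vocab = vocab
        self.bucket_specs = list(bucket_specs)
        self.cohort = list(cohort)
        if self.cohort:
            self.endog, self.valid_rows = encode_cohort(
                self.cohort, vocab, self.bucket_specs, max_T=config.max_T,
                clamp=True,
            )
        else:
            raise ValueError("cohort must be non-empty")

    @property
    def n_records(self) -> int:
        return len(self.cohort)

    def fit(
        self,
        epochs: int = 50,
        batch_size: int = 48,
        lr: float = 1e-4,
        seed: int = 0,
        verbose: bool = False,
    ) -> "HALOResults":
        """Train with Adam on masked binary cross-entropy.

        Defaults mirror the reference training recipe (learning rate 1e-4,
        batch size 48, 50 epochs).  Reproducible: the seed drives parameter
        initialization, shuffling and dropout.
        """
        ss = np.random.SeedSequence(seed)
        init_rng = np.random.default_rng(ss.spawn(1)[0])
        net = HALONetwork(self.config, len(self.vocab), rng=init_rng)
        trace = train_network(
            net, self.endog, self.valid_rows,
            epochs=epochs, batch_size=batch_size, lr=lr,
            seed=int(ss.generate_state(1)[0] % (2 ** 31)), verbose=verbose,
        )
        return HALOResults(model=self, network=net, loss_trace=trace,
                           fit_seed=seed, lr=lr, batch_size=batch_size)

    def untrained(self, seed: int = 0) -> "HALOResults":
        """Results wrapper around a freshly initialized (untrained) network;
        useful as a likelihood baseline."""
        net = HALONetwork(self.config, len(self.vocab),
                          rng=np.random.default_rng(seed))
        return HALOResults(model=self, network=net, loss_trace=[],
                           fit_seed=seed, lr=float("nan"), batch_size=0)


@dataclass
class HALOResults:
    """Trained parameters plus everything computed from them."""

    model: HALO
    network: HALONetwork
    loss_trace: list[float]
    fit_seed: int
    lr: float
    batch_size: int

    # -- conveniences ------------------------------------------------------

    @property
    def vocab(self) -> Vocabulary:
        return self.model.vocab

    @property
    def bucket_specs(self) -> list[BucketSpec]:
        return self.model.bucket_specs

    @property
    def config(self) -> HALOConfig:
        return self.network.config

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.network.params.values()))

    # -- generation --------------------------------------------------------

    def sample_cohort(
        self,
        n: int,
        seed: int = 0,
        condition_labels: Sequence[str] | None = None,
        max_T: int | None = None,
        temperature: float = 1.0,
    ) -> list[PatientRecord]:
        """Generate ``n`` synthetic records (optionally label-conditioned)."""
        spec = GenerationSpec(
            n_records=n,
            condition_labels=(frozenset(condition_labels)
                              if condition_labels is not None else None),
            max_T=max_T, seed=seed, temperature=temperature,
        )
        return sample_cohort(self.network, self.vocab, spec, self.bucket_specs)

    def sample_matrices(self, n: int, seed: int = 0, **kwargs):
        spec = GenerationSpec(n_records=n, seed=seed, **kwargs)
        return sample_matrices(self.network, self.vocab, spec,
                               self.bucket_specs)[0]

    # -- likelihood & metrics ----------------------------------------------

    def _encode(self, cohort: Sequence[PatientRecord] | None):
        if cohort is None:
            return self.model.endog, self.model.valid_rows
        return encode_cohort(cohort, self.vocab, self.bucket_specs,
                             max_T=self.config.max_T, clamp=True)

    def log_likelihood(self, record: PatientRecord | RecordMatrix) -> float:
        if isinstance(record, PatientRecord):
            record = encode_record(record, self.vocab, self.bucket_specs,
                                   max_T=self.config.max_T, clamp=True)
        return float(self.network.log_likelihoods(record.bits,
                                                  record.valid_rows)[0])

    def log_likelihoods(self, cohort: Sequence[PatientRecord] | None = None
                        ) -> np.ndarray:
        R, valid = self._encode(cohort)
        return self.network.log_likelihoods(R, valid)

    def perplexity(self, cohort: Sequence[PatientRecord] | None = None) -> float:
        """Per-present-code perplexity (training cohort by default)."""
        R, valid = self._encode(cohort)
        return _fidelity.perplexity_per_code(self.network, R, valid)

    def code_prediction_metrics(self, cohort=None, threshold: float = 0.5):
        R, valid = self._encode(cohort)
        return _fidelity.code_prediction_metrics(self.network, R, valid,
                                                 threshold=threshold)

    def fidelity_report(self, synthetic: Sequence[PatientRecord],
                        level: str = "record",
                        cohort: Sequence[PatientRecord] | None = None):
        real = self.model.cohort if cohort is None else list(cohort)
        return _fidelity.fidelity_report(
            real, synthetic, level=level, bucket_specs=self.bucket_specs,
            net=self.network, encoded=self._encode(cohort),
        )

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Hierarchical autoregressive EHR generator",
            "=" * 45,
            f"records (training)      {self.model.n_records}",
            f"vocabulary size |C|     {len(self.vocab)}",
            f"visit-level blocks M    {cfg.M}",
            f"code-level layers N     {cfg.N}" + ("  (coarse: disabled)"
                                                  if cfg.coarse else ""),
            f"embedding width         {cfg.n_emb}",
            f"attention heads         {cfg.n_heads}",
            f"max visits per record   {cfg.max_T}",
            f"parameters              {self.n_parameters():,}",
            f"optimizer               Adam(lr={self.lr}), batch {self.batch_size}",
            f"epochs                  {len(self.loss_trace)}",
        ]
        if self.loss_trace:
            lines.append(f"first-epoch mean loss   {self.loss_trace[0]:.6f}")
            lines.append(f"final-epoch mean loss   {self.loss_trace[-1]:.6f}")
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        save_checkpoint(path, self.network, self.vocab, self.bucket_specs,
                        extra={"loss_trace": self.loss_trace,
                               "fit_seed": self.fit_seed, "lr": self.lr,
                               "batch_size": self.batch_size})

    @classmethod
    def load(cls, path: str | Path,
             cohort: Sequence[PatientRecord] | None = None) -> "HALOResults":
        """Load a checkpoint.  If the training cohort is supplied the full
        results surface is available; otherwise only generation and
        per-cohort evaluation methods work."""
        net, vocab, specs, extra = load_checkpoint(path)
        if cohort is None:
            model = object.__new__(HALO)
            model.config = net.config
            model.vocab = vocab
            model.bucket_specs = specs
            model.cohort = []
            model.endog = model.valid_rows = None
        else:
            model = HALO(cohort, vocab, specs, config=net.config)
        return cls(model=model, network=net,
                   loss_trace=list(extra.get("loss_trace", [])),
                   fit_seed=extra.get("fit_seed", -1),
                   lr=extra.get("lr", float("nan")),
                   batch_size=extra.get("batch_size", 0))
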
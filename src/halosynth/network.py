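"""Two-level hierarchical autoregressive network over binary visit matrices.

The generative model factorizes the probability of a patient-record matrix
first over rows (visits) and then over columns (codes) within each row:

    P(R) = prod_t prod_i P(c_ti | rows < t, codes < i of row t)

Two modules realize this factorization:

* a *visit-level* module — a stack of ``M`` pre-norm transformer decoder
  blocks with causally masked self-attention — turns the embedded row
  sequence into per-row history vectors ``H``; row ``t`` of ``H`` depends
  only on input rows ``<= t``;
* a *code-level* module — ``N`` masked linear layers — concatenates history
  row ``t`` with the (offset) next input row and produces per-code Bernoulli
  probabilities.  Upper-triangular weight masks keep code ``i``'s output a
  function of the history and of codes ``< i`` only; the final layer's mask
  has a zero diagonal within the code block so no code sees its own input
  bit.

Everything here is plain numpy with hand-written backpropagation: forward
caches are dictionaries, gradients mirror the parameter dictionary, and
optimization is Adam.  The ``coarse`` variant replaces the code-level module
by a single unmasked linear map from the history alone (no intra-visit
conditioning), which is the ablation used to quantify the value of
code-level modeling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import erf

__all__ = [
    "HALOConfig",
    "HALONetwork",
    "masked_bce_loss",
    "record_log_likelihood",
    "train_network",
]

_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


@dataclass
class HALOConfig:
    """Architecture and numerical configuration.

    ``n_emb`` must be divisible by ``n_heads``.  ``prob_floor`` is the
    clipping epsilon applied to probabilities before any logarithm.
    """

    M: int = 12
    N: int = 2
    n_emb: int = 768
    n_heads: int = 12
    max_T: int = 100
    coarse: bool = False
    dropout: float = 0.1
    prob_floor: float = 1e-12

    def __post_init__(self) -> None:
        if self.M < 1 or self.N < 1:
            raise ValueError("M and N must be >= 1")
        if self.n_emb % self.n_heads:
            raise ValueError("n_emb must be divisible by n_heads")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if not 0.0 < self.prob_floor <= 1e-6:
            raise ValueError("prob_floor must be in (0, 1e-6]")

    @property
    def seq_len(self) -> int:
        # start + label + max_T visits + end
        return self.max_T + 3

    def to_dict(self) -> dict:
        return {
            "M": self.M, "N": self.N, "n_emb": self.n_emb,
            "n_heads": self.n_heads, "max_T": self.max_T,
            "coarse": self.coarse, "dropout": self.dropout,
            "prob_floor": self.prob_floor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HALOConfig":
        return cls(**d)


# ---------------------------------------------------------------------------
# primitive layers (forward + backward)
# ---------------------------------------------------------------------------

def _layernorm_fwd(x, g, b, eps=1e-5):
    mu = x.mean(-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    return g * xhat + b, (xhat, inv, g)


def _layernorm_bwd(dy, cache):
    xhat, inv, g = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    m1 = dxhat.mean(-1, keepdims=True)
    m2 = (dxhat * xhat).mean(-1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    return dx, dg, db


def _gelu_fwd(x):
    c = 0.5 * (1.0 + erf(x / _SQRT2))
    return x * c, (x, c)


def _gelu_bwd(dy, cache):
    x, c = cache
    return dy * (c + x * np.exp(-0.5 * x * x) * _INV_SQRT_2PI)


def _softmax_last(x):
    m = x.max(-1, keepdims=True)
    e = np.exp(x - m)
    return e / e.sum(-1, keepdims=True)


def _dropout_mask(shape, p, rng):
    if p <= 0.0 or rng is None:
        return None
    return (rng.random(shape) >= p).astype(np.float64) / (1.0 - p)


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def build_fine_masks(n_emb: int, n_codes: int, n_layers: int) -> list[np.ndarray]:
    """Upper-triangular autoregressive masks for the code-level layers.

    With ``y = x @ (W * mask)``, entry ``mask[i, j]`` gates input unit ``i``
    feeding output unit ``j``.  All layers use the upper triangle including
    the diagonal except the last, whose diagonal is zeroed within the code
    block: output code ``i`` must never see input bit ``i``.  History
    (embedding-portion) inputs are never blocked from code outputs because
    they sit strictly above the code block in the triangle.
    """
    d = n_emb + n_codes
    masks = []
    for n in range(n_layers):
        m = np.triu(np.ones((d, d)))
        if n == n_layers - 1:
            idx = np.arange(n_emb, d)
            m[idx, idx] = 0.0
        masks.append(m)
    return masks


def check_fine_masks(masks: Sequence[np.ndarray], n_emb: int) -> None:
    """Verify the mask invariant; raise ``ValueError`` if violated."""
    for n, m in enumerate(masks):
        d = m.shape[0]
        if m.shape != (d, d):
            raise ValueError("mask must be square")
        if np.any(np.tril(m, k=-1) != 0):
            raise ValueError(f"mask {n}: nonzero below the diagonal")
        strict = np.triu(np.ones_like(m), k=1)
        if np.any((m * strict) != strict):
            raise ValueError(f"mask {n}: zeros above the diagonal")
        diag = np.diag(m)
        if n < len(masks) - 1:
            if np.any(diag != 1):
                raise ValueError(f"mask {n}: diagonal must be all ones")
        else:
            if np.any(diag[n_emb:] != 0):
                raise ValueError("final mask: code-block diagonal must be zero")
            if np.any(diag[:n_emb] != 1):
                raise ValueError("final mask: embedding-block diagonal must be one")


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

class HALONetwork:
    """Parameter container plus forward/backward passes.

    Parameters are a flat ``dict[str, np.ndarray]``.  ``n_codes`` is the
    vocabulary size ``|C|``.
    """

    def __init__(self, config: HALOConfig, n_codes: int,
                 rng: np.random.Generator | None = None):
        self.config = config
        self.n_codes = int(n_codes)
        self.fine_masks = build_fine_masks(config.n_emb, self.n_codes, config.N)
        if rng is None:
            rng = np.random.default_rng(0)
        self.params = self._init_params(rng)

    def _init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        cfg, C = self.config, self.n_codes
        E = cfg.n_emb
        sd = 0.02

        def w(*shape):
            return rng.normal(0.0, sd, size=shape)

        p: dict[str, np.ndarray] = {
            "We": w(C, E),
            "Wp": w(cfg.seq_len, E),
            "lnf_g": np.ones(E), "lnf_b": np.zeros(E),
        }
        for m in range(cfg.M):
            p[f"blk{m}.ln1_g"] = np.ones(E)
            p[f"blk{m}.ln1_b"] = np.zeros(E)
            p[f"blk{m}.Wqkv"] = w(E, 3 * E)
            p[f"blk{m}.bqkv"] = np.zeros(3 * E)
            p[f"blk{m}.Wo"] = w(E, E)
            p[f"blk{m}.bo"] = np.zeros(E)
            p[f"blk{m}.ln2_g"] = np.ones(E)
            p[f"blk{m}.ln2_b"] = np.zeros(E)
            p[f"blk{m}.W1"] = w(E, 4 * E)
            p[f"blk{m}.b1"] = np.zeros(4 * E)
            p[f"blk{m}.W2"] = w(4 * E, E)
            p[f"blk{m}.b2"] = np.zeros(E)
        if cfg.coarse:
            p["coarse.W"] = w(E, C)
            p["coarse.b"] = np.zeros(C)
        else:
            D = E + C
            for n in range(cfg.N):
                p[f"fine{n}.W"] = w(D, D) * self.fine_masks[n]
                p[f"fine{n}.b"] = np.zeros(D)
        return p

    # -- visit-level module ------------------------------------------------

    def visit_histories(self, R: np.ndarray, train: bool = False,
                        rng: np.random.Generator | None = None,
                        cache: dict | None = None) -> np.ndarray:
        """Run the transformer stack; returns ``H`` of shape ``(B, L, n_emb)``.

        Row ``t`` of the output depends only on input rows ``<= t``.
        When ``cache`` is supplied it is filled with the forward
        intermediates needed for backpropagation.
        """
        cfg, p = self.config, self.params
        B, L, C = R.shape
        if C != self.n_codes:
            raise ValueError(f"input has {C} codes, network expects {self.n_codes}")
        if L > cfg.seq_len:
            raise ValueError(f"sequence length {L} exceeds max {cfg.seq_len}")
        E, h = cfg.n_emb, cfg.n_heads
        dh = E // h
        drop = cfg.dropout if train else 0.0

        x = R @ p["We"] + p["Wp"][:L]
        if cache is not None:
            cache["R"] = R
            cache["L"] = L
            cache["blocks"] = []
        causal = np.triu(np.ones((L, L)), k=1).astype(bool)

        for m in range(cfg.M):
            bc: dict = {}
            a, bc["ln1"] = _layernorm_fwd(x, p[f"blk{m}.ln1_g"], p[f"blk{m}.ln1_b"])
            qkv = a @ p[f"blk{m}.Wqkv"] + p[f"blk{m}.bqkv"]
            q, k, v = np.split(qkv, 3, axis=-1)
            # (B, h, L, dh)
            q = q.reshape(B, L, h, dh).transpose(0, 2, 1, 3)
            k = k.reshape(B, L, h, dh).transpose(0, 2, 1, 3)
            v = v.reshape(B, L, h, dh).transpose(0, 2, 1, 3)
            s = q @ k.transpose(0, 1, 3, 2) / math.sqrt(dh)
            s = np.where(causal, -1e30, s)
            att = _softmax_last(s)
            o = att @ v  # (B, h, L, dh)
            o = o.transpose(0, 2, 1, 3).reshape(B, L, E)
            proj = o @ p[f"blk{m}.Wo"] + p[f"blk{m}.bo"]
            dm1 = _dropout_mask(proj.shape, drop, rng)
            if dm1 is not None:
                proj = proj * dm1
            x = x + proj
            b_in, bc["ln2"] = _layernorm_fwd(x, p[f"blk{m}.ln2_g"], p[f"blk{m}.ln2_b"])
            h1 = b_in @ p[f"blk{m}.W1"] + p[f"blk{m}.b1"]
            hg, gelu_cache = _gelu_fwd(h1)
            mo = hg @ p[f"blk{m}.W2"] + p[f"blk{m}.b2"]
            dm2 = _dropout_mask(mo.shape, drop, rng)
            if dm2 is not None:
                mo = mo * dm2
            x_out = x + mo
            if cache is not None:
                bc.update(a=a, q=q, k=k, v=v, att=att, o=o, dm1=dm1,
                          b_in=b_in, gelu=gelu_cache, hg=hg, dm2=dm2)
                cache["blocks"].append(bc)
            x = x_out

        H, lnf_cache = _layernorm_fwd(x, p["lnf_g"], p["lnf_b"])
        if cache is not None:
            cache["lnf"] = lnf_cache
        return H

    def _histories_bwd(self, dH: np.ndarray, cache: dict,
                       grads: dict[str, np.ndarray]) -> None:
        cfg, p = self.config, self.params
        B, L, E = dH.shape
        h = cfg.n_heads
        dh = E // h

        dx, dg, db = _layernorm_bwd(dH, cache["lnf"])
        grads["lnf_g"] += dg
        grads["lnf_b"] += db

        for m in reversed(range(cfg.M)):
            bc = cache["blocks"][m]
            # mlp branch
            dmo = dx.copy()
            if bc["dm2"] is not None:
                dmo = dmo * bc["dm2"]
            grads[f"blk{m}.W2"] += np.einsum("bld,ble->de", bc["hg"], dmo)
            grads[f"blk{m}.b2"] += dmo.sum((0, 1))
            dhg = dmo @ p[f"blk{m}.W2"].T
            dh1 = _gelu_bwd(dhg, bc["gelu"])
            grads[f"blk{m}.W1"] += np.einsum("bld,ble->de", bc["b_in"], dh1)
            grads[f"blk{m}.b1"] += dh1.sum((0, 1))
            db_in = dh1 @ p[f"blk{m}.W1"].T
            dx2, dg2, db2 = _layernorm_bwd(db_in, bc["ln2"])
            grads[f"blk{m}.ln2_g"] += dg2
            grads[f"blk{m}.ln2_b"] += db2
            dx = dx + dx2
            # attention branch
            dproj = dx.copy()
            if bc["dm1"] is not None:
                dproj = dproj * bc["dm1"]
            grads[f"blk{m}.Wo"] += np.einsum("bld,ble->de", bc["o"], dproj)
            grads[f"blk{m}.bo"] += dproj.sum((0, 1))
            do = dproj @ p[f"blk{m}.Wo"].T
            do = do.reshape(B, L, h, dh).transpose(0, 2, 1, 3)
            datt = do @ bc["v"].transpose(0, 1, 3, 2)
            dv = bc["att"].transpose(0, 1, 3, 2) @ do
            att = bc["att"]
            ds = att * (datt - (datt * att).sum(-1, keepdims=True))
            ds = ds / math.sqrt(dh)
            dq = ds @ bc["k"]
            dk = ds.transpose(0, 1, 3, 2) @ bc["q"]
            dqkv = np.concatenate(
                [t.transpose(0, 2, 1, 3).reshape(B, L, E) for t in (dq, dk, dv)],
                axis=-1,
            )
            grads[f"blk{m}.Wqkv"] += np.einsum("bld,ble->de", bc["a"], dqkv)
            grads[f"blk{m}.bqkv"] += dqkv.sum((0, 1))
            da = dqkv @ p[f"blk{m}.Wqkv"].T
            dx1, dg1, db1 = _layernorm_bwd(da, bc["ln1"])
            grads[f"blk{m}.ln1_g"] += dg1
            grads[f"blk{m}.ln1_b"] += db1
            dx = dx + dx1

        R = cache["R"]
        grads["We"] += np.einsum("blc,ble->ce", R, dx)
        grads["Wp"][: cache["L"]] += dx.sum(0)

    # -- code-level module -------------------------------------------------

    def code_probabilities(self, H: np.ndarray, R: np.ndarray,
                           cache: dict | None = None) -> np.ndarray:
        """Masked-linear stack producing per-code probabilities.

        Input row ``j`` of the stack is ``H[j] ++ R[j+1]``; output row ``j``
        estimates the Bernoulli probabilities of the codes of record row
        ``j + 1``.  Returns ``O`` of shape ``(B, L-1, |C|)``.
        """
        if self.config.coarse:
            raise ValueError("coarse networks have no code-level module")
        check_fine_masks(self.fine_masks, self.config.n_emb)
        E = self.config.n_emb
        p = self.params
        x = np.concatenate([H[:, :-1, :], R[:, 1:, :]], axis=-1)
        if cache is not None:
            cache["fine_inputs"] = []
        for n in range(self.config.N):
            w_eff = p[f"fine{n}.W"] * self.fine_masks[n]
            if cache is not None:
                cache["fine_inputs"].append(x)
            z = x @ w_eff + p[f"fine{n}.b"]
            if n < self.config.N - 1:
                if cache is not None:
                    cache.setdefault("fine_z", []).append(z)
                x = np.maximum(z, 0.0)
            else:
                logits = z[:, :, E:]
        O = 1.0 / (1.0 + np.exp(-logits))
        return O

    def _code_probabilities_bwd(self, dlogits: np.ndarray, cache: dict,
                                grads: dict[str, np.ndarray]) -> np.ndarray:
        """Backprop through the fine stack; returns gradient w.r.t. ``H``."""
        cfg, p = self.config, self.params
        E = cfg.n_emb
        B, Lm1, C = dlogits.shape
        dz = np.zeros((B, Lm1, E + C))
        dz[:, :, E:] = dlogits
        for n in reversed(range(cfg.N)):
            x = cache["fine_inputs"][n]
            w_eff = p[f"fine{n}.W"] * self.fine_masks[n]
            grads[f"fine{n}.W"] += np.einsum("bld,ble->de", x, dz) * self.fine_masks[n]
            grads[f"fine{n}.b"] += dz.sum((0, 1))
            dx = dz @ w_eff.T
            if n > 0:
                dz = dx * (cache["fine_z"][n - 1] > 0)
        dH = np.zeros((B, Lm1 + 1, E))
        dH[:, :-1, :] = dx[:, :, :E]
        return dH

    # -- full forward ------------------------------------------------------

    def forward(self, R: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Probability matrix ``O`` of shape ``(B, L-1, |C|)``.

        ``O[:, j]`` estimates record row ``j + 1``; the start row is never a
        target.  Deterministic in eval mode (``train=False``).
        """
        R = np.asarray(R, dtype=np.float64)
        if R.ndim == 2:
            R = R[None]
        H = self.visit_histories(R, train=train, rng=rng)
        if self.config.coarse:
            logits = H[:, :-1, :] @ self.params["coarse.W"] + self.params["coarse.b"]
            return 1.0 / (1.0 + np.exp(-logits))
        return self.code_probabilities(H, R)

    # -- loss & gradients --------------------------------------------------

    def loss_and_grads(self, R: np.ndarray, valid: np.ndarray,
                       train_rng: np.random.Generator | None = None
                       ) -> tuple[float, dict[str, np.ndarray]]:
        """Masked BCE loss and full parameter gradients for one batch."""
        cfg = self.config
        R = np.asarray(R, dtype=np.float64)
        valid = np.asarray(valid, dtype=np.float64)
        cache: dict = {}
        H = self.visit_histories(R, train=train_rng is not None, rng=train_rng,
                                 cache=cache)
        if cfg.coarse:
            logits = H[:, :-1, :] @ self.params["coarse.W"] + self.params["coarse.b"]
            O = 1.0 / (1.0 + np.exp(-logits))
        else:
            O = self.code_probabilities(H, R, cache=cache)

        targets = R[:, 1:, :]
        row_mask = valid[:, 1:]
        loss = masked_bce_loss(O, targets, row_mask, eps=cfg.prob_floor)

        denom = row_mask.sum() * self.n_codes
        dlogits = (O - targets) * row_mask[:, :, None] / denom

        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        if cfg.coarse:
            grads["coarse.W"] += np.einsum("bld,ble->de", H[:, :-1, :], dlogits)
            grads["coarse.b"] += dlogits.sum((0, 1))
            dH = np.zeros_like(H)
            dH[:, :-1, :] = dlogits @ self.params["coarse.W"].T
        else:
            dH = self._code_probabilities_bwd(dlogits, cache, grads)
        self._histories_bwd(dH, cache, grads)
        return loss, grads

    # -- likelihood --------------------------------------------------------

    def log_likelihoods(self, R: np.ndarray, valid: np.ndarray,
                        chunk: int = 256) -> np.ndarray:
        """Per-record log P(R): sum of Bernoulli log-probabilities of every
        code bit over valid non-start rows (present and absent codes both
        contribute)."""
        R = np.asarray(R, dtype=np.float64)
        valid = np.asarray(valid, dtype=np.float64)
        if R.ndim == 2:
            R, valid = R[None], valid[None]
        eps = self.config.prob_floor
        out = np.empty(R.shape[0])
        for lo in range(0, R.shape[0], chunk):
            hi = lo + chunk
            O = np.clip(self.forward(R[lo:hi]), eps, 1.0 - eps)
            t = R[lo:hi, 1:, :]
            ll = t * np.log(O) + (1.0 - t) * np.log1p(-O)
            out[lo:hi] = (ll * valid[lo:hi, 1:, None]).sum((1, 2))
        return out

    # -- persistence -------------------------------------------------------

    def state_dict(self) -> dict:
        return {"config": self.config.to_dict(), "n_codes": self.n_codes,
                "params": {k: v.copy() for k, v in self.params.items()}}

    @classmethod
    def from_state_dict(cls, state: dict) -> "HALONetwork":
        net = cls(HALOConfig.from_dict(state["config"]), state["n_codes"])
        for k in net.params:
            net.params[k] = np.asarray(state["params"][k], dtype=np.float64)
        return net


def masked_bce_loss(O: np.ndarray, targets: np.ndarray, row_mask: np.ndarray,
                    eps: float = 1e-12) -> float:
    """Mean binary cross-entropy over all code positions of valid rows.

    ``O`` and ``targets`` are ``(B, L-1, C)``; ``row_mask`` is ``(B, L-1)``
    with 1 on valid (non-start, non-padding) target rows.  Probabilities are
    clipped to ``[eps, 1 - eps]`` before the logarithms.
    """
    row_mask = np.asarray(row_mask, dtype=np.float64)
    if row_mask.sum() == 0:
        raise ValueError("no valid target rows")
    Oc = np.clip(O, eps, 1.0 - eps)
    bce = -(targets * np.log(Oc) + (1.0 - targets) * np.log1p(-Oc))
    denom = row_mask.sum() * O.shape[-1]
    return float((bce * row_mask[:, :, None]).sum() / denom)


def record_log_likelihood(network: HALONetwork, matrix) -> float:
    """Exact log-probability of one :class:`~halosynth.records.RecordMatrix`."""
    return float(network.log_likelihoods(matrix.bits, matrix.valid_rows)[0])


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class AdamState:
    m: dict[str, np.ndarray]
    v: dict[str, np.ndarray]
    t: int = 0


def _adam_step(params, grads, state: AdamState, lr, beta1=0.9, beta2=0.999,
               eps=1e-8):
    state.t += 1
    b1t = 1.0 - beta1 ** state.t
    b2t = 1.0 - beta2 ** state.t
    for k, g in grads.items():
        state.m[k] = beta1 * state.m[k] + (1.0 - beta1) * g
        state.v[k] = beta2 * state.v[k] + (1.0 - beta2) * g * g
        params[k] -= lr * (state.m[k] / b1t) / (np.sqrt(state.v[k] / b2t) + eps)


def train_network(
    network: HALONetwork,
    R: np.ndarray,
    valid: np.ndarray,
    epochs: int = 50,
    batch_size: int = 48,
    lr: float = 1e-4,
    seed: int = 0,
    verbose: bool = False,
) -> list[float]:
    """Train with Adam on masked BCE; returns per-epoch mean losses.

    Fully reproducible given ``seed`` (drives shuffling and dropout).
    Aborts with diagnostics if the loss goes non-finite.
    """
    n = R.shape[0]
    if n == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)
    state = AdamState(
        m={k: np.zeros_like(v) for k, v in network.params.items()},
        v={k: np.zeros_like(v) for k, v in network.params.items()},
    )
    trace: list[float] = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, batch_size):
            idx = order[lo:lo + batch_size]
            loss, grads = network.loss_and_grads(R[idx], valid[idx], train_rng=rng)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss {loss} at epoch {epoch}, batch {lo // batch_size}"
                )
            _adam_step(network.params, grads, state, lr)
            losses.append(loss)
        trace.append(float(np.mean(losses)))
        if verbose:
            print(f"epoch {epoch + 1:3d}/{epochs}  loss {trace[-1]:.6f}")
    if not network.config.coarse:
        check_fine_masks(network.fine_masks, network.config.n_emb)
        for nlayer in range(network.config.N):
            w = network.params[f"fine{nlayer}.W"]
            if np.any(w * (1.0 - network.fine_masks[nlayer]) != 0):
                raise AssertionError("mask invariant violated after training")
    return trace
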
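"""Survival feature (SurvF) construction.

A small feed-forward network is trained to minimize the negative log Cox
partial likelihood (Breslow handling of tied times) on the clinical table
fused with the mRS-selected radiomics features, using age as the event
time and an mRS-derived indicator (default: poor outcome, mRS >= 3) as the
event.  The trained risk score, range-normalized across the cohort, is the
per-sample survival feature.  Training quality is tracked with the
concordance index.

The network is plain numpy (ReLU hidden layers, linear risk output,
hand-written backprop, Adam); everything is deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .significance import normalize

__all__ = [
    "SurvivalConfig", "CoxRiskNet", "cox_partial_likelihood_loss",
    "cox_loss_gradient", "concordance_index", "train_survival_net",
    "compute_survf", "default_event_rule",
]

log = logging.getLogger(__name__)


def default_event_rule(mrs7) -> np.ndarray:
    """Event indicator from the 7-level mRS: poor outcome (mRS >= 3)."""
    return (np.asarray(mrs7) >= 3).astype(int)


@dataclass(frozen=True)
class SurvivalConfig:
    epochs: int = 4000
    batch_size: int = 20
    hidden_layout: tuple = (32, 16)
    learning_rate: float = 1e-3
    event_threshold: int = 3        # event = (mRS >= threshold)
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if not 0 <= self.event_threshold <= 6:
            raise ValueError("event_threshold must map the 0..6 mRS range")


# ---------------------------------------------------------------------------
# Cox partial likelihood

def _risk_set_logsumexp(risks: np.ndarray, times: np.ndarray) -> np.ndarray:
    """log sum_{j: t_j >= t_i} exp(r_j) for every i (Breslow: ties share the
    full risk set)."""
    order = np.argsort(-times, kind="stable")
    r_sorted = risks[order]
    # cumulative logsumexp over descending time
    lse_sorted = np.empty_like(r_sorted)
    run = -np.inf
    for i, r in enumerate(r_sorted):
        run = np.logaddexp(run, r)
        lse_sorted[i] = run
    # ties: every sample with the same time gets the largest (full) risk set
    t_sorted = times[order]
    i = 0
    n = len(t_sorted)
    while i < n:
        j = i
        while j + 1 < n and t_sorted[j + 1] == t_sorted[i]:
            j += 1
        lse_sorted[i:j + 1] = lse_sorted[j]
        i = j + 1
    out = np.empty_like(lse_sorted)
    out[order] = lse_sorted
    return out


def cox_partial_likelihood_loss(risks, times, events) -> float:
    """Negative log Cox partial likelihood averaged over events:
    ``-(1/D) * sum_{i: event} [r_i - log sum_{j: t_j >= t_i} exp(r_j)]``.
    """
    risks = np.asarray(risks, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    d = int(events.sum())
    if d == 0:
        raise ValueError("no events in the data")
    lse = _risk_set_logsumexp(risks, times)
    return float(-np.sum(risks[events] - lse[events]) / d)


def cox_loss_gradient(risks, times, events) -> np.ndarray:
    """d loss / d risks for the Breslow partial likelihood."""
    risks = np.asarray(risks, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    d = int(events.sum())
    lse = _risk_set_logsumexp(risks, times)
    # sum over events i with t_i <= t_j of exp(r_j - lse_i)
    grad = np.zeros_like(risks)
    for i in np.flatnonzero(events):
        in_set = times >= times[i]
        grad[in_set] += np.exp(risks[in_set] - lse[i])
    grad[events] -= 1.0
    return grad / d


def concordance_index(risks, times, events) -> float:
    """Fraction of comparable pairs ordered correctly.

    A pair is comparable when the sample with the strictly shorter time has
    an event; it is concordant when that sample also has the higher
    predicted risk, with risk ties counting 0.5.
    """
    risks = np.asarray(risks, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    comp = (times[:, None] < times[None, :]) & events[:, None]
    n_comp = int(comp.sum())
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    higher = risks[:, None] > risks[None, :]
    tied = risks[:, None] == risks[None, :]
    return float((np.sum(comp & higher) + 0.5 * np.sum(comp & tied)) / n_comp)


# ---------------------------------------------------------------------------
# the network

class CoxRiskNet:
    """Feed-forward risk scorer: ReLU hidden layers, linear scalar output."""

    def __init__(self, n_in: int, hidden_layout=(32, 16), seed: int = 0):
        rng = np.random.default_rng(seed)
        dims = [n_in, *hidden_layout, 1]
        self.W = [rng.normal(0.0, np.sqrt(2.0 / dims[i]),
                             size=(dims[i], dims[i + 1]))
                  for i in range(len(dims) - 1)]
        self.b = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]

    def forward(self, X: np.ndarray, cache: list | None = None) -> np.ndarray:
        a = X
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            if cache is not None:
                cache.append(a)
            z = a @ W + b
            a = np.maximum(z, 0.0) if i < len(self.W) - 1 else z
        return a[:, 0]

    def backward(self, cache: list, grad_out: np.ndarray):
        """Gradients of sum(grad_out * risk) w.r.t. all parameters."""
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        delta = grad_out[:, None]
        for i in reversed(range(len(self.W))):
            a = cache[i]
            if i < len(self.W) - 1:
                z = a @ self.W[i] + self.b[i]
                delta = delta * (z > 0)
            gW[i] = a.T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.W[i].T
        return gW, gb

    # light-weight persistence
    def state(self) -> dict:
        return {"W": [w.copy() for w in self.W],
                "b": [b.copy() for b in self.b]}

    def load_state(self, state: dict):
        self.W = [np.asarray(w, dtype=float) for w in state["W"]]
        self.b = [np.asarray(b, dtype=float) for b in state["b"]]

    def save(self, path):
        np.savez(path, n_layers=len(self.W),
                 **{f"W{i}": w for i, w in enumerate(self.W)},
                 **{f"b{i}": b for i, b in enumerate(self.b)})

    @classmethod
    def load(cls, path) -> "CoxRiskNet":
        data = np.load(path)
        n = int(data["n_layers"])
        net = cls.__new__(cls)
        net.W = [data[f"W{i}"] for i in range(n)]
        net.b = [data[f"b{i}"] for i in range(n)]
        return net


def train_survival_net(features: pd.DataFrame | np.ndarray, times, events,
                       config: SurvivalConfig | None = None) -> tuple:
    """Minibatch Adam on the Cox loss.

    Returns ``(net, history)`` where history records the full-cohort loss
    and training C-index at checkpoints.  Batches without an event are
    skipped (the partial likelihood is undefined there).  Divergence
    (non-finite loss) raises.
    """
    config = config or SurvivalConfig()
    X = np.asarray(features, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    if events.sum() == 0:
        raise ValueError("no events; cannot fit a Cox model")
    rng = np.random.default_rng(config.seed)
    net = CoxRiskNet(X.shape[1], config.hidden_layout, seed=config.seed)

    mW = [np.zeros_like(w) for w in net.W]
    vW = [np.zeros_like(w) for w in net.W]
    mb = [np.zeros_like(b) for b in net.b]
    vb = [np.zeros_like(b) for b in net.b]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    history = []
    n = len(times)
    check_every = max(config.epochs // 20, 1)
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            if events[idx].sum() == 0:
                continue
            cache: list = []
            risks = net.forward(X[idx], cache)
            grad = cox_loss_gradient(risks, times[idx], events[idx])
            gW, gb = net.backward(cache, grad)
            step += 1
            for i in range(len(net.W)):
                mW[i] = beta1 * mW[i] + (1 - beta1) * gW[i]
                vW[i] = beta2 * vW[i] + (1 - beta2) * gW[i] ** 2
                mb[i] = beta1 * mb[i] + (1 - beta1) * gb[i]
                vb[i] = beta2 * vb[i] + (1 - beta2) * gb[i] ** 2
                mh = mW[i] / (1 - beta1 ** step)
                vh = vW[i] / (1 - beta2 ** step)
                net.W[i] -= config.learning_rate * mh / (np.sqrt(vh) + eps)
                mhb = mb[i] / (1 - beta1 ** step)
                vhb = vb[i] / (1 - beta2 ** step)
                net.b[i] -= config.learning_rate * mhb / (np.sqrt(vhb) + eps)
        if epoch % check_every == 0 or epoch == config.epochs - 1:
            risks = net.forward(X)
            loss = cox_partial_likelihood_loss(risks, times, events)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"Cox training diverged at epoch {epoch}")
            history.append({"epoch": epoch, "loss": loss,
                            "c_index": concordance_index(risks, times,
                                                         events)})
    return net, pd.DataFrame(history)


def compute_survf(net: CoxRiskNet, features: pd.DataFrame | np.ndarray
                  ) -> np.ndarray:
    """Raw risk per sample, range-normalized across the cohort
    ((r - mean)/(max - min); all-zero when the model output is constant)."""
    risks = net.forward(np.asarray(features, dtype=float))
    return normalize(risks)
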
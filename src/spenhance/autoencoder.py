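"""Joint embedding of spatial and reference cells with a two-layer auto-encoder.

A single fully connected layer projects the (S ∪ U)-dimensional
expression of every cell into a latent space (1000 dimensions by
default); a second fully connected layer decodes it back.  Both layers
use the rectifier, so embeddings and reconstructions are non-negative,
matching the log-normalized inputs.

The training loss has two parts, and each mini-batch is passed through
the network twice to form them:

* ``l1`` — squared-error reconstruction of the shared genes S for the
  spatial cells in the batch (their U entries are zero by construction).
* ``l2`` — squared error of the predicted U expression for the
  reference cells in the batch after masking their U input to zero,
  with errors at zero entries of the target down-weighted by Q, the
  non-zero fraction of the reference data: the sparser the reference,
  the more likely a zero is a dropout rather than true absence.

The total is ``l1 + alpha * l2`` with ``alpha = (NS*MT)/(NU*MR)``
equalizing the per-element contribution of the two parts (NS/NU gene
counts, MT/MR per-batch cell counts).  After training, the snapshots
from the epochs with minimal loss are retained and later ensembled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import ORIGIN_SPATIAL, MergedTrainingSet


@dataclass
class ModelConfig:
    """Auto-encoder architecture and training schedule."""

    latent_dim: int = 1000
    epochs: int = 100
    batch_size: int = 512
    learning_rate: float = 1e-3
    seed: int = 0
    n_snapshots: int = 5

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.n_snapshots > self.epochs:
            raise ValueError(
                f"n_snapshots ({self.n_snapshots}) exceeds epochs ({self.epochs})"
            )


@dataclass
class BatchLoss:
    l1: float
    l2: float
    alpha: float
    total: float


@dataclass
class Snapshot:
    """Parameters captured at the end of one epoch."""

    epoch: int
    loss: float
    params: dict[str, np.ndarray]


@dataclass
class TrainedModel:
    snapshots: list[Snapshot]
    loss_trace: np.ndarray
    gene_order: list[str]
    config: ModelConfig

    def embeddings(self, cells: np.ndarray) -> list[np.ndarray]:
        """Embed ``cells`` (rows over S∪U, training gene order) per snapshot."""
        return [embed(s, cells) for s in self.snapshots]


def loss_part1(es: np.ndarray, es_hat: np.ndarray) -> float:
    """Sum of squared errors over the spatial cells' shared genes."""
    es = np.asarray(es, dtype=float)
    es_hat = np.asarray(es_hat, dtype=float)
    if es.shape != es_hat.shape:
        raise ValueError(f"shape mismatch: {es.shape} vs {es_hat.shape}")
    if es.size == 0:
        return 0.0
    return float(np.sum((es - es_hat) ** 2))


def loss_part2(eu: np.ndarray, eu_hat: np.ndarray, q: float) -> float:
    """Sparsity-penalized squared error over the reference cells' U genes.

    Errors at zero entries of the target are multiplied by ``q`` (the
    non-zero fraction of the reference data).
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"Q outside [0,1]: {q}")
    eu = np.asarray(eu, dtype=float)
    eu_hat = np.asarray(eu_hat, dtype=float)
    if eu.shape != eu_hat.shape:
        raise ValueError(f"shape mismatch: {eu.shape} vs {eu_hat.shape}")
    if eu.size == 0:
        return 0.0
    gamma = np.where(eu == 0, q, 1.0)
    return float(np.sum(gamma * (eu - eu_hat) ** 2))


def compute_alpha(ns: int, nu: int, mt_batch: int, mr_batch: int) -> float:
    """Loss balance alpha = (NS * MT_batch) / (NU * MR_batch).

    A batch without spatial cells gives alpha = 0 (the l1 term is empty
    too); a batch without reference cells must skip l2 entirely, so a
    zero denominator is an error here.
    """
    if mt_batch == 0:
        return 0.0
    if nu <= 0 or mr_batch <= 0:
        raise ZeroDivisionError(
            f"alpha undefined for NU={nu}, MR_batch={mr_batch}; "
            "skip the l2 term when the batch has no reference cells"
        )
    return (ns * mt_batch) / (nu * mr_batch)


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0, out=x)


class AutoEncoder:
    """Two-layer rectified auto-encoder trained with Adam.

    Weights use the uniform fan-in initialization U(-1/sqrt(fan_in),
    1/sqrt(fan_in)) from a seeded generator; all arithmetic is float32.
    """

    def __init__(self, input_dim: int, latent_dim: int, rng: np.random.Generator):
        def init(fan_in: int, shape: tuple[int, ...]) -> np.ndarray:
            bound = 1.0 / np.sqrt(fan_in)
            return rng.uniform(-bound, bound, size=shape).astype(np.float32)

        self.params = {
            "W1": init(input_dim, (input_dim, latent_dim)),
            "b1": init(input_dim, (latent_dim,)),
            "W2": init(latent_dim, (latent_dim, input_dim)),
            "b2": init(latent_dim, (input_dim,)),
        }
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        p = self.params
        h = _relu(x @ p["W1"] + p["b1"])
        y = _relu(h @ p["W2"] + p["b2"])
        return h, y

    def _backward(
        self, x: np.ndarray, h: np.ndarray, y: np.ndarray, dy: np.ndarray
    ) -> dict[str, np.ndarray]:
        p = self.params
        dy = dy * (y > 0)
        dh = (dy @ p["W2"].T) * (h > 0)
        return {
            "W2": h.T @ dy,
            "b2": dy.sum(axis=0),
            "W1": x.T @ dh,
            "b1": dh.sum(axis=0),
        }

    def adam_step(
        self,
        grads: dict[str, np.ndarray],
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            m = self._adam_m[k]
            v = self._adam_v[k]
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            self.params[k] -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(np.float32)

    def snapshot_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}


def train_step(
    model: AutoEncoder,
    x_spatial: np.ndarray,
    x_reference: np.ndarray,
    n_shared: int,
    q: float,
    lr: float,
) -> BatchLoss:
    """One optimizer update from a mixed batch; returns the batch loss.

    The batch is fed forward twice: once as-is for the spatial rows
    (l1 on the S columns) and once with the reference rows' U columns
    masked to zero (l2 on the U columns).  A batch lacking one origin
    contributes only the other loss part.
    """
    n_sp, n_ref = x_spatial.shape[0], x_reference.shape[0]
    if n_sp == 0 and n_ref == 0:
        raise ValueError("empty batch")
    dim = (x_spatial if n_sp else x_reference).shape[1]
    nu = dim - n_shared
    grads = {k: np.zeros_like(v) for k, v in model.params.items()}

    l1 = 0.0
    if n_sp:
        h1, y1 = model.forward(x_spatial)
        es, es_hat = x_spatial[:, :n_shared], y1[:, :n_shared]
        l1 = loss_part1(es, es_hat)
        dy1 = np.zeros_like(y1)
        dy1[:, :n_shared] = 2.0 * (es_hat - es)
        for k, g in model._backward(x_spatial, h1, y1, dy1).items():
            grads[k] += g

    l2 = 0.0
    alpha = 0.0
    if n_ref and nu > 0:
        alpha = compute_alpha(n_shared, nu, n_sp, n_ref) if n_sp else 0.0
        x_masked = x_reference.copy()
        x_masked[:, n_shared:] = 0.0
        h2, y2 = model.forward(x_masked)
        eu, eu_hat = x_reference[:, n_shared:], y2[:, n_shared:]
        l2 = loss_part2(eu, eu_hat, q)
        if alpha > 0:
            gamma = np.where(eu == 0, q, 1.0).astype(x_masked.dtype)
            dy2 = np.zeros_like(y2)
            dy2[:, n_shared:] = 2.0 * alpha * gamma * (eu_hat - eu)
            for k, g in model._backward(x_masked, h2, y2, dy2).items():
                grads[k] += g

    total = l1 + alpha * l2
    if not np.isfinite(total):
        raise FloatingPointError(f"non-finite batch loss (l1={l1}, l2={l2})")
    model.adam_step(grads, lr)
    return BatchLoss(l1=l1, l2=l2, alpha=alpha, total=total)


def fit(merged: MergedTrainingSet, cfg: ModelConfig) -> TrainedModel:
    """Train on the merged set and keep the minimal-loss epoch snapshots.

    The epoch loss used to rank snapshots is the mean of batch total
    losses over the epoch; training runs for a fixed epoch budget and
    the ``n_snapshots`` lowest-loss epochs are retained for ensembling.
    """
    if cfg.epochs < cfg.n_snapshots:
        raise ValueError("epochs must be >= n_snapshots")
    rng = np.random.default_rng(cfg.seed)
    x = np.ascontiguousarray(merged.matrix, dtype=np.float32)
    is_spatial = merged.origin == ORIGIN_SPATIAL
    n = x.shape[0]
    model = AutoEncoder(x.shape[1], cfg.latent_dim, rng)

    trace = np.empty(cfg.epochs)
    best: list[Snapshot] = []
    for epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            sp = idx[is_spatial[idx]]
            rf = idx[~is_spatial[idx]]
            try:
                loss = train_step(
                    model, x[sp], x[rf], merged.n_shared, merged.q_nonzero,
                    cfg.learning_rate,
                )
            except FloatingPointError as exc:
                raise FloatingPointError(
                    f"epoch {epoch}, batch {start // cfg.batch_size}: {exc}"
                ) from exc
            batch_losses.append(loss.total)
        trace[epoch] = float(np.mean(batch_losses))
        best.append(Snapshot(epoch, trace[epoch], model.snapshot_params()))
        best.sort(key=lambda s: (s.loss, s.epoch))
        del best[cfg.n_snapshots :]

    return TrainedModel(
        snapshots=best, loss_trace=trace,
        gene_order=list(merged.gene_order), config=cfg,
    )


def embed(snapshot: Snapshot, cells: np.ndarray) -> np.ndarray:
    """Project cells (rows over S∪U in training gene order) into latent space."""
    w1, b1 = snapshot.params["W1"], snapshot.params["b1"]
    cells = np.asarray(cells, dtype=np.float32)
    if cells.shape[1] != w1.shape[0]:
        raise ValueError(
            f"input width {cells.shape[1]} does not match model input {w1.shape[0]}"
        )
    return np.maximum(cells @ w1 + b1, 0.0)
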
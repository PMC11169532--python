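"""Variational autoencoder for per-population expression generation.

A single VAE is trained on all cells of a labeled expression dataset.
The encoder is a four-layer MLP (2048, 1024, 512, 256 units, ReLU after
every layer except the last) feeding linear heads for the posterior mean
mu and log-variance; the decoder mirrors it (512, 1024, 2048, k units)
with a ReLU after every layer including the last, so decoded expression
is non-negative by construction. The latent space has 128 dimensions by
default and the training objective is the negative ELBO: a Gaussian
reconstruction term (squared error on normalized expression, unit
observation variance) plus the analytic KL divergence between the
diagonal-Gaussian posterior q(z|x) = N(mu, diag(sigma^2)) and the
standard-normal prior.

Population conditioning is post hoc: after training, the encoder means
of each population's cells are summarized by a diagonal Gaussian in
latent space, and new cells of a population are generated by sampling z
from that Gaussian and decoding. Distinct populations occupy distinct
regions of the latent space, so per-population sampling reproduces
per-population expression statistics.

The network and its Adam optimizer are implemented directly on NumPy
arrays; everything is seeded and runs on a single CPU.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_io import ExpressionDataset, validate_dataset


@dataclass
class VAEConfig:
    """Architecture and optimization settings for :func:`train_vae`.

    ``encoder_widths`` / ``decoder_widths`` are the hidden-layer sizes;
    the decoder's final width is always the gene count and is appended
    automatically. ``latent_dim`` is the dimensionality of z.
    """

    latent_dim: int = 128
    encoder_widths: list[int] = field(default_factory=lambda: [2048, 1024, 512, 256])
    decoder_widths: list[int] = field(default_factory=lambda: [512, 1024, 2048])
    epochs: int = 200
    batch_size: int = 128
    learning_rate: float = 1e-3
    #: fraction of epochs over which the KL weight ramps linearly 0 -> 1
    #: (KL warm-up guards against posterior collapse on small datasets)
    kl_warmup_frac: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim <= 0:
            raise ValueError("latent_dim must be positive")
        if self.epochs <= 0 or self.batch_size <= 0 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")

    def to_dict(self) -> dict:
        return {
            "latent_dim": self.latent_dim,
            "encoder_widths": list(self.encoder_widths),
            "decoder_widths": list(self.decoder_widths),
            "epochs": self.epochs,
            "batch_size": self.batch_size,
            "learning_rate": self.learning_rate,
            "kl_warmup_frac": self.kl_warmup_frac,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# Minimal dense network machinery
# ---------------------------------------------------------------------------


class _Dense:
    """Fully connected layer with cached forward pass for backprop."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # He initialization, appropriate for ReLU stacks
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self._x: np.ndarray | None = None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        if cache:
            self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._x is not None
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class _ReLU:
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if cache:
            self._mask = x > 0
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._mask is not None
        return grad * self._mask


class _Adam:
    def __init__(self, layers, lr: float):
        self.layers = [l for l in layers if isinstance(l, _Dense)]
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = [
            [np.zeros_like(p) for p, _ in layer.params()] for layer in self.layers
        ]
        self.v = [
            [np.zeros_like(p) for p, _ in layer.params()] for layer in self.layers
        ]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for li, layer in enumerate(self.layers):
            for pi, (p, g) in enumerate(layer.params()):
                m = self.m[li][pi]
                v = self.v[li][pi]
                m *= self.beta1
                m += (1 - self.beta1) * g
                v *= self.beta2
                v += (1 - self.beta2) * g * g
                p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _stack(widths: list[int], rng: np.random.Generator, final_relu: bool):
    """Dense/ReLU stack over consecutive width pairs."""
    layers: list = []
    for i in range(len(widths) - 1):
        layers.append(_Dense(widths[i], widths[i + 1], rng))
        if i < len(widths) - 2 or final_relu:
            layers.append(_ReLU())
    return layers


def _forward(layers, x: np.ndarray, cache: bool = True) -> np.ndarray:
    for layer in layers:
        x = layer.forward(x, cache=cache)
    return x


def _backward(layers, grad: np.ndarray) -> np.ndarray:
    for layer in reversed(layers):
        grad = layer.backward(grad)
    return grad


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


@dataclass
class LatentSummary:
    """Diagonal Gaussian fitted to one population's encoder means."""

    mean: np.ndarray
    var: np.ndarray
    n_cells: int


class TrainedModel:
    """Trained VAE weights plus per-population latent summaries."""

    def __init__(self, cfg: VAEConfig, gene_names: list[str]):
        self.cfg = cfg
        self.gene_names = list(gene_names)
        k = len(gene_names)
        rng = np.random.default_rng(cfg.seed)
        enc_widths = [k] + list(cfg.encoder_widths)
        # no ReLU after the last encoder layer; mu / logvar heads are linear
        self.encoder = _stack(enc_widths, rng, final_relu=False)
        h = enc_widths[-1]
        self.head_mu = _Dense(h, cfg.latent_dim, rng)
        self.head_logvar = _Dense(h, cfg.latent_dim, rng)
        # start with a small posterior sd (~0.14) so early training behaves
        # like a plain autoencoder and the latent code becomes informative
        # before the KL weight ramps in; guards against posterior collapse
        self.head_logvar.b[:] = -4.0
        # ReLU after every decoder layer, including the output layer, so
        # generated expression is non-negative
        dec_widths = [cfg.latent_dim] + list(cfg.decoder_widths) + [k]
        self.decoder = _stack(dec_widths, rng, final_relu=True)
        self.latent_summaries: dict[str, LatentSummary] = {}

    # -- inference ---------------------------------------------------------

    def encode(self, x: np.ndarray, cache: bool = False):
        """Posterior parameters (mu, logvar) for a batch of cells."""
        h = _forward(self.encoder, np.atleast_2d(x), cache=cache)
        mu = self.head_mu.forward(h, cache=cache)
        logvar = self.head_logvar.forward(h, cache=cache)
        return mu, np.clip(logvar, -15.0, 15.0)

    def decode(self, z: np.ndarray, cache: bool = False) -> np.ndarray:
        return _forward(self.decoder, np.atleast_2d(z), cache=cache)

    def _all_layers(self):
        return self.encoder + [self.head_mu, self.head_logvar] + self.decoder

    # -- persistence ---------------------------------------------------------

    def save(self, path: str) -> None:
        """Write weights + latent summaries to a single ``.npz`` checkpoint
        with a JSON config sidecar for inspection."""
        arrays: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self._all_layers()):
            if isinstance(layer, _Dense):
                arrays[f"W{i}"] = layer.W
                arrays[f"b{i}"] = layer.b
        for pop, summ in self.latent_summaries.items():
            arrays[f"latmean::{pop}"] = summ.mean
            arrays[f"latvar::{pop}"] = summ.var
            arrays[f"latn::{pop}"] = np.array([summ.n_cells])
        arrays["gene_names"] = np.array(self.gene_names)
        np.savez_compressed(path, **arrays)
        sidecar = path + ".json" if not path.endswith(".npz") else path[:-4] + ".json"
        with open(sidecar, "w") as fh:
            json.dump(self.cfg.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path: str) -> "TrainedModel":
        sidecar = path + ".json" if not path.endswith(".npz") else path[:-4] + ".json"
        with open(sidecar) as fh:
            cfg = VAEConfig(**json.load(fh))
        data = np.load(path, allow_pickle=False)
        gene_names = [str(g) for g in data["gene_names"]]
        model = cls(cfg, gene_names)
        for i, layer in enumerate(model._all_layers()):
            if isinstance(layer, _Dense):
                layer.W = data[f"W{i}"]
                layer.b = data[f"b{i}"]
        pops = {k.split("::", 1)[1] for k in data.files if k.startswith("latmean::")}
        for pop in pops:
            model.latent_summaries[pop] = LatentSummary(
                mean=data[f"latmean::{pop}"],
                var=data[f"latvar::{pop}"],
                n_cells=int(data[f"latn::{pop}"][0]),
            )
        return model


# ---------------------------------------------------------------------------
# Loss pieces
# ---------------------------------------------------------------------------


def gaussian_kl(mu: np.ndarray, logvar: np.ndarray) -> float:
    """Analytic KL( N(mu, diag(exp(logvar))) || N(0, I) ), summed over
    dimensions and averaged over rows.

    The closed form per dimension is ``0.5 * (mu^2 + sigma^2 - 1 - log sigma^2)``,
    which is >= 0 with equality iff mu = 0 and sigma = 1.
    """
    mu = np.atleast_2d(mu)
    logvar = np.atleast_2d(logvar)
    kl = 0.5 * np.sum(mu**2 + np.exp(logvar) - 1.0 - logvar, axis=1)
    return float(kl.mean())


def reparameterize(mu: np.ndarray, sigma: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """z = mu + sigma * eps, elementwise."""
    mu, sigma, eps = np.asarray(mu), np.asarray(sigma), np.asarray(eps)
    if not (mu.shape == sigma.shape == eps.shape):
        raise ValueError("mu, sigma and eps must share a shape")
    if np.any(sigma < 0):
        raise ValueError("sigma must be non-negative")
    return mu + sigma * eps


def elbo_loss(
    batch: np.ndarray, model: TrainedModel, eps: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Negative ELBO of a batch: 0.5 * ||x - xhat||^2 + KL, averaged over rows.

    One Monte-Carlo sample of z per datum; pass ``eps`` for a deterministic
    evaluation.
    """
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    if batch.shape[1] != len(model.gene_names):
        raise ValueError(
            f"batch has {batch.shape[1]} genes, model expects {len(model.gene_names)}"
        )
    mu, logvar = model.encode(batch)
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(logvar))):
        bad = np.argwhere(~np.isfinite(mu).all(axis=1) | ~np.isfinite(logvar).all(axis=1))
        raise FloatingPointError(f"non-finite activations for batch rows {bad.ravel().tolist()}")
    sigma = np.exp(0.5 * logvar)
    if eps is None:
        rng = rng or np.random.default_rng()
        eps = rng.standard_normal(mu.shape)
    z = reparameterize(mu, sigma, eps)
    xhat = model.decode(z)
    recon = 0.5 * np.sum((batch - xhat) ** 2, axis=1).mean()
    return float(recon + gaussian_kl(mu, logvar))


# ---------------------------------------------------------------------------
# Training and generation
# ---------------------------------------------------------------------------


def train_vae(ds: ExpressionDataset, cfg: VAEConfig | None = None) -> TrainedModel:
    """Train the VAE and fit per-population latent Gaussians.

    Returns a :class:`TrainedModel` whose ``loss_history`` attribute holds
    the per-epoch mean training loss.
    """
    cfg = cfg or VAEConfig()
    report = validate_dataset(ds)
    if report:
        raise ValueError("invalid dataset: " + "; ".join(report))
    X = np.asarray(ds.matrix, dtype=float)
    n, k = X.shape
    model = TrainedModel(cfg, ds.gene_names)
    # start the output layer alive: small weights, bias at the per-gene data
    # mean, so the final ReLU does not zero out (and kill the gradient of)
    # genes that are expressed
    out_layer = next(
        l for l in reversed(model.decoder) if isinstance(l, _Dense)
    )
    out_layer.W *= 0.1
    out_layer.b = X.mean(axis=0).copy()
    opt = _Adam(model._all_layers(), cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)

    history: list[float] = []
    warmup = max(1, int(round(cfg.kl_warmup_frac * cfg.epochs)))
    for epoch in range(cfg.epochs):
        beta = min(1.0, (epoch + 1) / warmup)
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            xb = X[order[start : start + cfg.batch_size]]
            m = xb.shape[0]
            # forward with caches
            h = _forward(model.encoder, xb, cache=True)
            mu = model.head_mu.forward(h, cache=True)
            logvar = np.clip(model.head_logvar.forward(h, cache=True), -15.0, 15.0)
            sigma = np.exp(0.5 * logvar)
            eps = rng.standard_normal(mu.shape)
            z = mu + sigma * eps
            xhat = _forward(model.decoder, z, cache=True)
            if not np.all(np.isfinite(xhat)):
                raise FloatingPointError(
                    f"non-finite activations in batch starting at index {start}"
                )
            recon = 0.5 * np.sum((xb - xhat) ** 2, axis=1).mean()
            kl = gaussian_kl(mu, logvar)
            epoch_loss += recon + kl  # history tracks the unweighted ELBO
            n_batches += 1
            # backward; all loss terms averaged over the batch, KL scaled
            # by the warm-up weight beta
            dxhat = (xhat - xb) / m
            dz = _backward(model.decoder, dxhat)
            dmu = dz + beta * mu / m
            # dz/dlogvar = 0.5 * sigma * eps;  dKL/dlogvar = 0.5 (sigma^2 - 1)
            dlogvar = dz * 0.5 * sigma * eps + beta * 0.5 * (np.exp(logvar) - 1.0) / m
            dh = model.head_mu.backward(dmu) + model.head_logvar.backward(dlogvar)
            _backward(model.encoder, dh)
            opt.step()
        history.append(epoch_loss / max(n_batches, 1))

    model.loss_history = history  # type: ignore[attr-defined]

    # per-population diagonal Gaussian over the encoder means
    mus, _ = model.encode(X)
    pops = np.asarray(ds.population)
    for pop in sorted(set(ds.population)):
        sub = mus[pops == pop]
        if sub.shape[0] < 2:
            warnings.warn(
                f"population {pop!r} has a single cell; latent variance set to 1",
                stacklevel=2,
            )
            var = np.ones(cfg.latent_dim)
        else:
            var = sub.var(axis=0, ddof=1)
        model.latent_summaries[pop] = LatentSummary(
            mean=sub.mean(axis=0), var=var, n_cells=sub.shape[0]
        )
    return model


def generate_cells(
    model: TrainedModel, population: str, count: int, seed: int = 0
) -> ExpressionDataset:
    """Sample ``count`` new cells of one population.

    z is drawn from the population's latent Gaussian and decoded; output is
    non-negative by the decoder's final ReLU and reproducible under ``seed``.
    """
    if population not in model.latent_summaries:
        raise KeyError(
            f"unknown population {population!r}; "
            f"model knows {sorted(model.latent_summaries)}"
        )
    k = len(model.gene_names)
    if count == 0:
        return ExpressionDataset(
            matrix=np.zeros((0, k)), gene_names=model.gene_names,
            cell_ids=[], population=[],
        )
    summ = model.latent_summaries[population]
    rng = np.random.default_rng(seed)
    z = summ.mean + np.sqrt(summ.var) * rng.standard_normal(
        (count, model.cfg.latent_dim)
    )
    X = model.decode(z)
    return ExpressionDataset(
        matrix=X,
        gene_names=model.gene_names,
        cell_ids=[f"{population}_sim_{i}" for i in range(count)],
        population=[population] * count,
    )
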
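"""Variational autoencoder pretraining of 256-d node embeddings.

One autoencoder per node type: species are encoded from their abundance
profile across samples, samples from their composition across species. The
latent layer is variational (Gaussian) because the KL regularizer weight
(``kl_coef``) only has meaning for a distributional code; the deterministic
posterior mean is used as the embedding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._optim import Adam

logger = logging.getLogger(__name__)


@dataclass
class PretrainResult:
    embeddings: np.ndarray            # (n_nodes, embedding_dim): species rows then samples
    rec_trace_species: list[float]    # per-epoch reconstruction MSE
    rec_trace_samples: list[float]


def _init(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    return rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / (fan_in + fan_out))


def _train_vae(
    X: np.ndarray,
    latent_dim: int,
    hidden_dim: int,
    lr: float,
    kl_coef: float,
    epochs: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[float]]:
    """Fit a single-hidden-layer VAE on standardized features; return the
    posterior means (n, latent_dim) and the per-epoch reconstruction trace."""
    n, F = X.shape
    mu_x, sd_x = X.mean(), X.std()
    Xs = (X - mu_x) / (sd_x + 1e-12)
    if latent_dim > F:
        logger.info("over-complete latent: embedding_dim %d > feature dim %d", latent_dim, F)

    p = {
        "W1": _init(rng, F, hidden_dim), "b1": np.zeros(hidden_dim),
        "Wm": _init(rng, hidden_dim, latent_dim), "bm": np.zeros(latent_dim),
        "Wl": _init(rng, hidden_dim, latent_dim), "bl": np.zeros(latent_dim),
        "W2": _init(rng, latent_dim, hidden_dim), "b2": np.zeros(hidden_dim),
        "W3": _init(rng, hidden_dim, F), "b3": np.zeros(F),
    }
    opt = Adam(p, lr=lr)
    trace: list[float] = []
    for _ in range(epochs):
        h1 = np.tanh(Xs @ p["W1"] + p["b1"])
        mu = h1 @ p["Wm"] + p["bm"]
        lv_pre = h1 @ p["Wl"] + p["bl"]
        lv = np.clip(lv_pre, -10.0, 10.0)
        eps = rng.standard_normal(mu.shape)
        z = mu + np.exp(0.5 * lv) * eps
        h2 = np.tanh(z @ p["W2"] + p["b2"])
        Xh = h2 @ p["W3"] + p["b3"]

        rec = float(np.mean((Xh - Xs) ** 2))
        if not np.isfinite(rec):
            raise FloatingPointError(
                f"autoencoder reconstruction loss became non-finite at epoch {len(trace)}"
            )
        trace.append(rec)

        dXh = 2.0 * (Xh - Xs) / Xs.size
        g = {}
        g["W3"] = h2.T @ dXh
        g["b3"] = dXh.sum(0)
        dh2 = dXh @ p["W3"].T
        dz2 = dh2 * (1 - h2 * h2)
        g["W2"] = z.T @ dz2
        g["b2"] = dz2.sum(0)
        dz = dz2 @ p["W2"].T
        # KL(q||N(0,1)) term, averaged over rows
        dmu = dz + kl_coef * mu / n
        dlv = dz * eps * 0.5 * np.exp(0.5 * lv) + kl_coef * 0.5 * (np.exp(lv) - 1.0) / n
        dlv *= (np.abs(lv_pre) < 10.0)
        dh1 = dmu @ p["Wm"].T + dlv @ p["Wl"].T
        g["Wm"] = h1.T @ dmu
        g["bm"] = dmu.sum(0)
        g["Wl"] = h1.T @ dlv
        g["bl"] = dlv.sum(0)
        da1 = dh1 * (1 - h1 * h1)
        g["W1"] = Xs.T @ da1
        g["b1"] = da1.sum(0)
        opt.step(g)

    h1 = np.tanh(Xs @ p["W1"] + p["b1"])
    emb = h1 @ p["Wm"] + p["bm"]
    return emb, trace


def pretrain_autoencoders(graph, config, rng: np.random.Generator | None = None) -> PretrainResult:
    """Train the two node-type autoencoders and return stacked initial
    embeddings (species rows first, then samples), each ``embedding_dim`` wide."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    emb_sp, tr_sp = _train_vae(
        graph.species_features, config.embedding_dim, config.n_hid,
        config.learning_rate, config.kl_coef, config.ae_epochs, rng,
    )
    emb_sa, tr_sa = _train_vae(
        graph.sample_features, config.embedding_dim, config.n_hid,
        config.learning_rate, config.kl_coef, config.ae_epochs, rng,
    )
    return PretrainResult(np.vstack([emb_sp, emb_sa]), tr_sp, tr_sa)
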
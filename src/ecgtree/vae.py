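"""Annealed beta-VAE over median-beat ECGs.

Convolutional encoder (six conv blocks, max pooling after every second block,
one final conv, then a fully connected layer to the latent moments) with a
mirror-symmetric decoder.  Objective per batch (both terms per sample, so
they are on commensurate scales):

    sum_elements |x - x_hat|  +  beta * | KL(q(z|x) || N(0, I)) - C(t) |

with the channel capacity C(t) annealed linearly from 0 to ``capacity_max``
over the first ``capacity_anneal_epochs`` epochs, then held constant.  This
encourages latent units to be introduced sequentially, yielding a compact set
of informative (KL > threshold) units used by all downstream stages.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict, field

import numpy as np

from .nn import Adam, Conv1d, Dense, MaxPool2, ReLU, Sequential, Upsample2
from .preprocess import BEAT_LEN

N_LEADS = 8


@dataclass
class VAEConfig:
    latent_dim: int = 256
    beta: float = 10.0
    capacity_max: float = 30.0          # nats
    capacity_anneal_epochs: int | None = None   # default: half the epochs
    epochs: int = 200
    batch: int = 128
    lr: float = 5e-4
    split: tuple[int, int, int] = (85, 5, 10)
    info_threshold: float = 0.1         # nats
    widths: tuple[int, int, int] = (32, 64, 128)
    kernel: int = 5
    seed: int = 0

    def __post_init__(self):
        if sum(self.split) != 100:
            raise ValueError("split fractions must sum to 100")
        if self.beta <= 0 or self.info_threshold <= 0:
            raise ValueError("beta and info_threshold must be positive")
        if self.capacity_anneal_epochs is None:
            self.capacity_anneal_epochs = max(1, self.epochs // 2)


def desk_config(**over) -> VAEConfig:
    """Reduced-width configuration for desk-scale cohorts (minutes on 1 CPU)."""
    kw = dict(latent_dim=24, widths=(12, 16, 24), epochs=80,
              capacity_max=50.0, capacity_anneal_epochs=10, seed=0)
    kw.update(over)
    return VAEConfig(**kw)


def paper_config(**over) -> VAEConfig:
    """Full-width configuration (latent 256, 200 epochs)."""
    kw = dict(latent_dim=256, widths=(32, 64, 128), epochs=200, seed=0)
    kw.update(over)
    return VAEConfig(**kw)


def capacity_at(epoch: int, cfg: VAEConfig) -> float:
    """Annealed capacity C(t): linear 0 -> capacity_max, then constant."""
    frac = min(1.0, epoch / max(1, cfg.capacity_anneal_epochs))
    return cfg.capacity_max * frac


def kl_per_unit(z_mean: np.ndarray, z_logvar: np.ndarray) -> np.ndarray:
    """Closed-form per-unit KL(q || N(0,1)) = 0.5 (mu^2 + sigma^2 - 1 - log sigma^2)."""
    return 0.5 * (z_mean ** 2 + np.exp(z_logvar) - 1.0 - z_logvar)


@dataclass
class LatentCode:
    z_mean: np.ndarray
    z_logvar: np.ndarray
    per_unit_kl: np.ndarray


class ConvVAE:
    """Encoder/decoder pair; all state lives in the two Sequential stacks."""

    def __init__(self, cfg: VAEConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        c1, c2, c3 = cfg.widths
        k = cfg.kernel
        self.bottleneck_len = BEAT_LEN // 8   # three poolings
        self.encoder = Sequential([
            Conv1d(N_LEADS, c1, k, rng), ReLU(),
            Conv1d(c1, c1, k, rng), ReLU(), MaxPool2(),
            Conv1d(c1, c2, k, rng), ReLU(),
            Conv1d(c2, c2, k, rng), ReLU(), MaxPool2(),
            Conv1d(c2, c3, k, rng), ReLU(),
            Conv1d(c3, c3, k, rng), ReLU(), MaxPool2(),
            Conv1d(c3, c3, k, rng), ReLU(),
        ])
        self.enc_fc = Dense(c3 * self.bottleneck_len, 2 * cfg.latent_dim, rng)
        self.dec_fc = Dense(cfg.latent_dim, c3 * self.bottleneck_len, rng)
        self.dec_fc_relu = ReLU()
        self.decoder = Sequential([
            Conv1d(c3, c3, k, rng), ReLU(), Upsample2(),
            Conv1d(c3, c3, k, rng), ReLU(),
            Conv1d(c3, c2, k, rng), ReLU(), Upsample2(),
            Conv1d(c2, c2, k, rng), ReLU(),
            Conv1d(c2, c1, k, rng), ReLU(), Upsample2(),
            Conv1d(c1, c1, k, rng), ReLU(),
            Conv1d(c1, N_LEADS, k, rng),
        ])
        self._modules = [self.encoder, Sequential([self.enc_fc]),
                         Sequential([self.dec_fc]), self.decoder]

    def n_params(self) -> tuple[int, int]:
        enc = self.encoder.n_params() + sum(p.size for p in self.enc_fc.params)
        dec = self.decoder.n_params() + sum(p.size for p in self.dec_fc.params)
        return enc, dec

    # ---- forward passes -------------------------------------------------
    def encode_moments(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = self.encoder.forward(x.astype(np.float32))
        self._enc_shape = h.shape
        h = h.reshape(h.shape[0], -1)
        out = self.enc_fc.forward(h)
        d = self.cfg.latent_dim
        # upper clip just above the prior scale: posterior variances beyond
        # the prior carry no information but destabilise capacity annealing
        mu, logvar = out[:, :d], np.clip(out[:, d:], -12.0, 1.0)
        return mu, logvar

    def decode(self, z: np.ndarray) -> np.ndarray:
        h = self.dec_fc_relu.forward(self.dec_fc.forward(z.astype(np.float32)))
        c3 = self.cfg.widths[2]
        h = h.reshape(z.shape[0], c3, self.bottleneck_len)
        return self.decoder.forward(h)

    # ---- training -------------------------------------------------------
    def _backward(self, x, x_hat, mu, logvar, eps, kl_sign):
        bsz = x.shape[0]
        cfg = self.cfg
        dxhat = np.sign(x_hat - x).astype(np.float32) / bsz
        dh = self.decoder.backward(dxhat)
        dh = dh.reshape(bsz, -1)
        dz = self.dec_fc.backward(self.dec_fc_relu.backward(dh))
        # KL path (mean total KL over batch)
        s = cfg.beta * kl_sign / bsz
        sigma2 = np.exp(logvar)
        dmu = dz + s * mu
        dlogvar = dz * eps * 0.5 * np.exp(0.5 * logvar) + s * 0.5 * (sigma2 - 1.0)
        dout = np.concatenate([dmu, dlogvar], axis=1).astype(np.float32)
        dhenc = self.enc_fc.backward(dout)
        self.encoder.backward(dhenc.reshape(self._enc_shape))

    def train_step(self, x, capacity, opt: Adam, rng: np.random.Generator):
        cfg = self.cfg
        mu, logvar = self.encode_moments(x)
        eps = rng.standard_normal(mu.shape).astype(np.float32)
        z = mu + eps * np.exp(0.5 * logvar)
        x_hat = self.decode(z)
        # per-sample summed absolute error, averaged over the batch
        recon = float(np.sum(np.abs(x_hat - x))) / x.shape[0]
        kl_total = float(np.mean(kl_per_unit(mu, logvar).sum(axis=1)))
        loss = recon + cfg.beta * abs(kl_total - capacity)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"NaN/inf loss (recon={recon}, kl={kl_total}); "
                "lower the learning rate or capacity_max")
        opt.zero_grad()
        self._backward(x, x_hat, mu, logvar, eps, np.sign(kl_total - capacity))
        opt.step()
        return loss, recon, kl_total

    # ---- persistence ----------------------------------------------------
    def save(self, path: str) -> None:
        arrays, meta = {}, {"cfg": asdict(self.cfg)}
        for mi, mod in enumerate(self._modules):
            for li, layer in enumerate(mod.param_layers):
                for pi, p in enumerate(layer.params):
                    arrays[f"m{mi}_l{li}_p{pi}"] = p
        np.savez(path, __meta__=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str) -> "ConvVAE":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["__meta__"]))
        cfgd = meta["cfg"]
        cfgd["split"] = tuple(cfgd["split"])
        cfgd["widths"] = tuple(cfgd["widths"])
        model = cls(VAEConfig(**cfgd))
        for mi, mod in enumerate(model._modules):
            for li, layer in enumerate(mod.param_layers):
                for pi in range(len(layer.params)):
                    layer.params[pi][...] = data[f"m{mi}_l{li}_p{pi}"]
        return model


# --------------------------------------------------------------------------
# training / evaluation API


def grouped_split(patient_ids, split=(85, 5, 10), seed: int = 0):
    """Patient-grouped train/val/test index split (no patient spans splits)."""
    patient_ids = np.asarray(patient_ids)
    uniq = np.unique(patient_ids)
    rng = np.random.default_rng(seed)
    rng.shuffle(uniq)
    n = len(uniq)
    n_tr = int(round(n * split[0] / 100))
    n_va = int(round(n * split[1] / 100))
    tr_p = set(uniq[:n_tr].tolist())
    va_p = set(uniq[n_tr:n_tr + n_va].tolist())
    te_p = set(uniq[n_tr + n_va:].tolist())
    if tr_p & va_p or tr_p & te_p or va_p & te_p:
        raise RuntimeError("patient leakage across splits")
    idx = np.arange(len(patient_ids))
    return (idx[np.isin(patient_ids, list(tr_p))],
            idx[np.isin(patient_ids, list(va_p))],
            idx[np.isin(patient_ids, list(te_p))])


@dataclass
class TrainingTrace:
    loss: list = field(default_factory=list)
    recon: list = field(default_factory=list)
    kl: list = field(default_factory=list)
    capacity: list = field(default_factory=list)
    val_recon: list = field(default_factory=list)
    val_per_unit_kl: np.ndarray | None = None


def train_vae(beats: np.ndarray, patient_ids, cfg: VAEConfig
              ) -> tuple[ConvVAE, TrainingTrace, tuple]:
    """Train the annealed beta-VAE on (N, 8, 320) median beats.

    Returns (model, trace, (train_idx, val_idx, test_idx)).  Deterministic for
    a fixed config seed under single-threaded execution.
    """
    beats = np.asarray(beats, dtype=np.float32)
    if beats.ndim != 3 or beats.shape[1] != N_LEADS:
        raise ValueError("beats must be (N, 8, L)")
    if len(beats) < 100:
        raise ValueError("need at least 100 beats to train")
    tr, va, te = grouped_split(patient_ids, cfg.split, seed=cfg.seed)
    model = ConvVAE(cfg)
    opt = Adam(model._modules, lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed + 1)
    trace = TrainingTrace()
    xtr = beats[tr]
    for epoch in range(cfg.epochs):
        cap = capacity_at(epoch, cfg)
        order = rng.permutation(len(xtr))
        ep_loss = ep_rec = ep_kl = 0.0
        nb = 0
        for start in range(0, len(xtr), cfg.batch):
            xb = xtr[order[start:start + cfg.batch]]
            if len(xb) < 2:
                continue
            l, r, k = model.train_step(xb, cap, opt, rng)
            ep_loss += l
            ep_rec += r
            ep_kl += k
            nb += 1
        trace.loss.append(ep_loss / nb)
        trace.recon.append(ep_rec / nb)
        trace.kl.append(ep_kl / nb)
        trace.capacity.append(cap)
        if len(va):
            mu, lv = encode_batch(model, beats[va])
            xh = decode_batch(model, mu)
            trace.val_recon.append(float(np.sum(np.abs(xh - beats[va]))) / len(va))
    if len(va):
        mu, lv = encode_batch(model, beats[va])
        trace.val_per_unit_kl = kl_per_unit(mu, lv).mean(axis=0)
    return model, trace, (tr, va, te)


def _batched(fn, x, batch=256):
    outs = [fn(x[i:i + batch]) for i in range(0, len(x), batch)]
    if isinstance(outs[0], tuple):
        return tuple(np.concatenate([o[j] for o in outs]) for j in range(len(outs[0])))
    return np.concatenate(outs)


def encode_batch(model: ConvVAE, beats: np.ndarray):
    """Deterministic posterior moments (no sampling) for a batch of beats."""
    return _batched(model.encode_moments, np.asarray(beats, dtype=np.float32))


def decode_batch(model: ConvVAE, z: np.ndarray):
    return _batched(model.decode, np.asarray(z, dtype=np.float32))


def encode(model: ConvVAE, beat: np.ndarray) -> LatentCode:
    """Encode one beat (8, L) or a batch (N, 8, L) to posterior moments + KL."""
    beat = np.asarray(beat, dtype=np.float32)
    single = beat.ndim == 2
    if single:
        beat = beat[None]
    if beat.shape[1:] != (N_LEADS, BEAT_LEN):
        raise ValueError(f"beat shape {beat.shape[1:]} != ({N_LEADS}, {BEAT_LEN})")
    mu, lv = encode_batch(model, beat)
    kl = kl_per_unit(mu, lv)
    if single:
        return LatentCode(mu[0], lv[0], kl[0])
    return LatentCode(mu, lv, kl)


def select_informative_units(model: ConvVAE, val_beats: np.ndarray,
                             threshold: float = 0.1) -> np.ndarray:
    """Units whose mean validation KL exceeds ``threshold`` nats, KL-descending."""
    if len(val_beats) == 0:
        raise ValueError("validation set is empty")
    mu, lv = encode_batch(model, val_beats)
    mean_kl = kl_per_unit(mu, lv).mean(axis=0)
    keep = np.where(mean_kl > threshold)[0]
    if keep.size == 0:
        raise RuntimeError(
            "no latent unit exceeds the information threshold; "
            "increase capacity_max or training length")
    return keep[np.argsort(-mean_kl[keep], kind="stable")]


def reconstruction_fidelity(model: ConvVAE, beats: np.ndarray
                            ) -> tuple[float, np.ndarray]:
    """Median (and per-record) Pearson r between beats and z_mean reconstructions."""
    beats = np.asarray(beats, dtype=np.float32)
    mu, _ = encode_batch(model, beats)
    xh = decode_batch(model, mu)
    rs = []
    for i in range(len(beats)):
        a, b = beats[i].ravel(), xh[i].ravel()
        if a.std() == 0:
            warnings.warn(f"record {i} has zero variance; skipped")
            continue
        rs.append(float(np.corrcoef(a, b)[0, 1]))
    rs = np.asarray(rs)
    return float(np.median(rs)), rs


def latent_traversal(model: ConvVAE, base_code: np.ndarray, unit: int,
                     retained_units: np.ndarray,
                     lo: float = -3.0, hi: float = 3.0, step: float = 0.5
                     ) -> np.ndarray:
    """Decode a grid varying one retained unit, others fixed at ``base_code``."""
    if step <= 0:
        raise ValueError("step must be positive")
    if unit not in set(int(u) for u in retained_units):
        raise ValueError(f"unit {unit} is not a retained unit")
    values = np.arange(lo, hi + step / 2, step)
    z = np.tile(np.asarray(base_code, dtype=np.float32), (len(values), 1))
    z[:, unit] = values
    return decode_batch(model, z)
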
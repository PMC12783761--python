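"""Reference baselines the heterogeneous federation is compared against.

Homogeneous parameter-averaging methods (FedAvg, FedProx, MOON) require all
clients to share the server architecture; heterogeneity-tolerant baselines
(FedProto prototype alignment, unidirectional knowledge distillation) keep
per-center architectures.  A pooled-data model (CDTM) and a multivariate
logistic clinical model (age, sex, smoking history, CEA status) complete the
comparison grid.  All federated baselines run on the same in-process harness
as the heterogeneous model: same datasets, same seeds, same evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import nn
from .backbones import Backbone, BackboneSpec, build_backbone
from .hfl_core import FederationConfig, _epoch_batches, _to_nchw
from .synthetic_cohort import CenterDataset

__all__ = [
    "ParamVector", "PrototypeSet", "fedavg_aggregate", "fedprox_local_step",
    "moon_contrastive_loss", "moon_loss_batch", "fedproto_round",
    "prototype_regularizer", "kd_distill_loss", "kd_loss_batch",
    "cdtm_train", "clinical_model_fit", "ClinicalModel",
    "run_homogeneous_federation", "run_kd_federation",
    "run_fedproto_federation",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class ParamVector:
    """Flattened parameter values plus a structural signature."""

    values: list[np.ndarray]
    signature: tuple[tuple[int, ...], ...]

    @classmethod
    def from_model(cls, model: Backbone) -> "ParamVector":
        return cls(values=model.state(), signature=model.signature())


def fedavg_aggregate(params: Sequence[ParamVector],
                     sizes: Sequence[int]) -> ParamVector:
    """Size-weighted arithmetic mean of identically structured parameters."""
    if len(params) != len(sizes) or not params:
        raise ValueError("need one positive size per parameter vector")
    if any(s <= 0 for s in sizes):
        raise ValueError("sizes must be positive")
    sig = params[0].signature
    if any(p.signature != sig for p in params):
        raise ValueError("cannot aggregate across different structural "
                         "signatures")
    w = np.asarray(sizes, dtype=float)
    w = w / w.sum()
    out = [np.zeros_like(a) for a in params[0].values]
    for wk, p in zip(w, params):
        for acc, arr in zip(out, p.values):
            acc += wk * arr
    return ParamVector(values=out, signature=sig)


# ---------------------------------------------------------------------------
# FedProx
# ---------------------------------------------------------------------------

def fedprox_local_step(model: Backbone, global_params: list[np.ndarray],
                       images: np.ndarray, labels: np.ndarray,
                       mu: float, lr: float) -> float:
    """One gradient step on CE + (mu/2) * ||w - w_global||^2; returns loss."""
    if mu < 0:
        raise ValueError("mu must be >= 0")
    model.set_training(True)
    x = nn.Tensor(_to_nchw(images))
    logits, _ = model.forward(x)
    loss = nn.softmax_cross_entropy(logits, np.asarray(labels, dtype=np.int64))
    opt = nn.SGD(model.parameters(), lr)
    opt.zero_grad()
    loss.backward()
    total = float(loss.data)
    if mu > 0:
        # prox applies to trainable weights only; gradient-free buffers
        # (batch-norm running statistics) are excluded
        for p, g in zip(model.parameters(), global_params):
            if p.grad is None:
                continue
            diff = p.data - g
            total += 0.5 * mu * float((diff ** 2).sum())
            p.grad += mu * diff
    opt.step()
    return total


# ---------------------------------------------------------------------------
# MOON contrastive loss
# ---------------------------------------------------------------------------

def moon_contrastive_loss(z_local: np.ndarray, z_global: np.ndarray,
                          z_previous: np.ndarray, tau: float) -> float:
    """-log( e^{cos(z,zg)/tau} / (e^{cos(z,zg)/tau} + e^{cos(z,zp)/tau}) )."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    z, zg, zp = (np.asarray(v, dtype=float).ravel()
                 for v in (z_local, z_global, z_previous))
    for v in (z, zg, zp):
        if np.linalg.norm(v) == 0:
            raise ValueError("zero-norm embedding")
    c1 = float(z @ zg / (np.linalg.norm(z) * np.linalg.norm(zg)))
    c2 = float(z @ zp / (np.linalg.norm(z) * np.linalg.norm(zp)))
    return float(np.log1p(np.exp((c2 - c1) / tau)))


def moon_loss_batch(z: nn.Tensor, z_global: np.ndarray,
                    z_previous: np.ndarray, tau: float) -> nn.Tensor:
    """Differentiable batch-mean MOON loss (gradient w.r.t. ``z`` only)."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    zd = z.data
    n = zd.shape[0]
    norms = np.linalg.norm(zd, axis=1, keepdims=True)
    if (norms == 0).any():
        raise ValueError("zero-norm embedding")
    gn = z_global / np.linalg.norm(z_global, axis=1, keepdims=True)
    pn = z_previous / np.linalg.norm(z_previous, axis=1, keepdims=True)
    zn = zd / norms
    c1 = (zn * gn).sum(axis=1)
    c2 = (zn * pn).sum(axis=1)
    s = 1.0 / (1.0 + np.exp(-(c2 - c1) / tau))   # sigmoid of the gap
    val = np.log1p(np.exp((c2 - c1) / tau)).mean()

    def bwd(out: nn.Tensor) -> None:
        # d cos(z,a)/dz = (a_n - cos * z_n) / |z|
        dc1 = (gn - c1[:, None] * zn) / norms
        dc2 = (pn - c2[:, None] * zn) / norms
        g = (s[:, None] * (dc2 - dc1)) / (tau * n)
        z._accumulate(out.grad * g)
    return nn._make(np.asarray(val), (z,), bwd)


# ---------------------------------------------------------------------------
# FedProto
# ---------------------------------------------------------------------------

@dataclass
class PrototypeSet:
    """Per-class embedding centroids with their sample counts."""

    centroids: dict[int, np.ndarray]
    counts: dict[int, int]

    def validate(self) -> None:
        if set(self.centroids) != set(self.counts):
            raise ValueError("centroid/count class mismatch")
        if any(c <= 0 for c in self.counts.values()):
            raise ValueError("counts must be positive")


def local_prototypes(embeddings: np.ndarray,
                     labels: np.ndarray) -> PrototypeSet:
    """Per-class mean embeddings of one client's samples."""
    labels = np.asarray(labels)
    cents, counts = {}, {}
    for cls in np.unique(labels):
        mask = labels == cls
        cents[int(cls)] = embeddings[mask].mean(axis=0)
        counts[int(cls)] = int(mask.sum())
    return PrototypeSet(cents, counts)


def fedproto_round(client_sets: Sequence[PrototypeSet]) -> PrototypeSet:
    """Count-weighted mean of client prototypes per class."""
    classes = sorted({c for ps in client_sets for c in ps.centroids})
    if not classes:
        raise ValueError("no class observed by any client")
    cents, counts = {}, {}
    for cls in classes:
        num, den = None, 0
        for ps in client_sets:
            if cls in ps.centroids:
                term = ps.counts[cls] * ps.centroids[cls]
                num = term if num is None else num + term
                den += ps.counts[cls]
        cents[cls] = num / den
        counts[cls] = den
    out = PrototypeSet(cents, counts)
    out.validate()
    return out


def prototype_regularizer(embedding: np.ndarray,
                          prototype: np.ndarray) -> float:
    """Squared distance of a sample's embedding to its class prototype."""
    d = np.asarray(embedding, dtype=float) - np.asarray(prototype, dtype=float)
    return float((d ** 2).sum())


# ---------------------------------------------------------------------------
# knowledge distillation
# ---------------------------------------------------------------------------

def kd_distill_loss(student_logits: np.ndarray, teacher_logits: np.ndarray,
                    temperature: float) -> float:
    """KL(softmax(teacher/T) || softmax(student/T)) * T^2 (nats)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    s = np.asarray(student_logits, dtype=float) / temperature
    t = np.asarray(teacher_logits, dtype=float) / temperature
    ls = s - np.log(np.exp(s - s.max()).sum()) - s.max()
    lt = t - np.log(np.exp(t - t.max()).sum()) - t.max()
    p = np.exp(lt)
    return float(temperature ** 2 * (p * (lt - ls)).sum())


def kd_loss_batch(student_logits: nn.Tensor, teacher_logits: np.ndarray,
                  temperature: float) -> nn.Tensor:
    """Differentiable batch-mean distillation loss (teacher is constant)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    T = temperature
    t = np.asarray(teacher_logits, dtype=float) / T
    s = student_logits.data / T
    n = s.shape[0]

    def logsoft(z):
        zm = z - z.max(axis=1, keepdims=True)
        return zm - np.log(np.exp(zm).sum(axis=1, keepdims=True))

    lt, ls = logsoft(t), logsoft(s)
    p, q = np.exp(lt), np.exp(ls)
    val = T ** 2 * (p * (lt - ls)).sum(axis=1).mean()

    def bwd(out: nn.Tensor) -> None:
        student_logits._accumulate(out.grad * T * (q - p) / n)
    return nn._make(np.asarray(val), (student_logits,), bwd)


# ---------------------------------------------------------------------------
# pooled-data training (CDTM)
# ---------------------------------------------------------------------------

def cdtm_train(datasets: Sequence[CenterDataset], spec: BackboneSpec,
               config: FederationConfig) -> Backbone:
    """Train a single model on the concatenation of every center's train set."""
    if not datasets:
        raise ValueError("no datasets to pool")
    images = np.concatenate([ds.pixels("train") for ds in datasets])
    labels = np.concatenate([ds.labels("train") for ds in datasets])
    model = build_backbone(spec)
    rng = np.random.default_rng(config.seed)
    opt = nn.SGD(model.parameters(), config.lr)
    model.set_training(True)
    epochs = config.rounds * config.local_epochs
    for _ in range(epochs):
        for bidx in _epoch_batches(rng, len(images), config.batch_size):
            x = nn.Tensor(_to_nchw(images[bidx]))
            logits, _ = model.forward(x)
            loss = nn.softmax_cross_entropy(logits, labels[bidx])
            opt.zero_grad()
            loss.backward()
            opt.step()
    model.set_training(False)
    return model


# ---------------------------------------------------------------------------
# clinical logistic model
# ---------------------------------------------------------------------------

@dataclass
class ClinicalModel:
    """Multivariate logistic model on (age, sex, smoking, cea)."""

    coef: np.ndarray             # 4 slopes
    intercept: float
    separation_warning: bool
    means: np.ndarray
    sds: np.ndarray

    def predict_proba(self, covariates: np.ndarray) -> np.ndarray:
        x = (np.asarray(covariates, dtype=float) - self.means) / self.sds
        z = x @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-z))


def clinical_model_fit(covariates: np.ndarray, labels: np.ndarray,
                       tol: float = 1e-8, max_iter: int = 200,
                       coef_cap: float = 15.0) -> ClinicalModel:
    """Maximum-likelihood logistic fit by iteratively reweighted least squares.

    Covariates are standardized internally (constant columns get unit scale).
    Perfect separation is reported as a warning state with coefficients
    capped at ``coef_cap`` on the standardized scale.
    """
    x = np.asarray(covariates, dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.ndim != 2 or len(x) != len(y):
        raise ValueError("covariates must be n x p aligned with labels")
    if not np.isfinite(x).all():
        raise ValueError("missing or non-finite covariates")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    means = x.mean(axis=0)
    sds = x.std(axis=0)
    sds[sds == 0] = 1.0
    xs = (x - means) / sds
    design = np.column_stack([np.ones(len(y)), xs])
    beta = np.zeros(design.shape[1])
    separated = False
    for _ in range(max_iter):
        eta = design @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        wdiag = p * (1 - p)
        if wdiag.min() < 1e-12:
            wdiag = np.maximum(wdiag, 1e-12)
        grad = design.T @ (y - p)
        hess = design.T @ (design * wdiag[:, None])
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            # singular design (e.g. constant covariates): min-norm step
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        beta_new = beta + step
        if np.abs(beta_new[1:]).max() > coef_cap:
            separated = True
            beta = np.clip(beta_new, -coef_cap, coef_cap)
            break
        if np.abs(step).max() < tol:
            beta = beta_new
            break
        beta = beta_new
    if separated:
        warnings.warn("possible perfect separation: coefficients capped",
                      RuntimeWarning, stacklevel=2)
    return ClinicalModel(coef=beta[1:], intercept=float(beta[0]),
                         separation_warning=separated, means=means, sds=sds)


# ---------------------------------------------------------------------------
# federated harnesses
# ---------------------------------------------------------------------------

def _embed(model: Backbone, images: np.ndarray) -> np.ndarray:
    """Final-stage average-pooled embedding (values only)."""
    last = model.spec.tap_stages[-1]
    return model.stage_features(images)[last]


def run_homogeneous_federation(method: str, datasets: Sequence[CenterDataset],
                               spec: BackboneSpec, config: FederationConfig,
                               mu: float = 0.01, moon_mu: float = 1.0,
                               moon_tau: float = 0.5
                               ) -> tuple[Backbone, list[dict]]:
    """FedAvg / FedProx / MOON: every center trains the server architecture.

    Each round: broadcast global parameters, local training per center with
    the method's objective, size-weighted parameter averaging.
    """
    if method not in ("fedavg", "fedprox", "moon"):
        raise ValueError(f"not a homogeneous parameter-averaging method: "
                         f"{method!r}")
    config.validate()
    global_model = build_backbone(spec)
    local = build_backbone(spec)
    sizes = [len(ds.train) for ds in datasets]
    prev_params: list[list[np.ndarray] | None] = [None] * len(datasets)
    prev_model = build_backbone(spec) if method == "moon" else None
    rngs = [np.random.default_rng(s)
            for s in np.random.SeedSequence(config.seed).spawn(len(datasets))]
    logs = []
    for rnd in range(config.rounds):
        collected = []
        round_losses = {}
        for i, ds in enumerate(datasets):
            images, labels = ds.pixels("train"), ds.labels("train")
            local.load_state(global_model.state())
            gparams = global_model.state()
            if method == "moon":
                z_glob = _embed(global_model, images)
                if prev_params[i] is not None:
                    prev_model.load_state(prev_params[i])
                    z_prev = _embed(prev_model, images)
                else:
                    z_prev = z_glob
            opt = nn.SGD(local.parameters(), config.lr)
            local.set_training(True)
            loss_val = 0.0
            nb = 0
            for _ in range(config.local_epochs):
                for bidx in _epoch_batches(rngs[i], len(images),
                                           config.batch_size):
                    if method == "fedprox":
                        loss_val += fedprox_local_step(
                            local, gparams, images[bidx], labels[bidx],
                            mu, config.lr)
                        nb += 1
                        continue
                    x = nn.Tensor(_to_nchw(images[bidx]))
                    logits, maps = local.forward(x)
                    loss = nn.softmax_cross_entropy(logits, labels[bidx])
                    if method == "moon":
                        z = nn.global_avg_pool(maps[spec.tap_stages[-1]])
                        closs = moon_loss_batch(z, z_glob[bidx], z_prev[bidx],
                                                moon_tau)
                        loss = nn.add(loss, nn.scale(closs, moon_mu))
                    opt.zero_grad()
                    loss.backward()
                    opt.step()
                    loss_val += float(loss.data)
                    nb += 1
            local.set_training(False)
            round_losses[ds.profile.center_id] = loss_val / nb
            prev_params[i] = local.state()
            collected.append(ParamVector.from_model(local))
        agg = fedavg_aggregate(collected, sizes)
        global_model.load_state(agg.values)
        logs.append(dict(round=rnd, losses=round_losses))
    return global_model, logs


def run_kd_federation(datasets: Sequence[CenterDataset], server_index: int,
                      specs: dict[str, BackboneSpec],
                      config: FederationConfig, lam_kd: float = 0.5,
                      temperature: float = 2.0
                      ) -> tuple[Backbone, dict[str, Backbone], list[dict]]:
    """Unidirectional distillation: global teacher soft-labels local students.

    The global model trains on the server center's data; each round every
    client minimizes CE + lam_kd * KD(student, teacher soft labels).
    """
    config.validate()
    ids = [ds.profile.center_id for ds in datasets]
    server_id = ids[server_index]
    global_model = build_backbone(specs["__global__"])
    local_models = {cid: build_backbone(specs[cid]) for cid in ids}
    seeds = np.random.SeedSequence(config.seed).spawn(len(ids) + 1)
    rngs = dict(zip(ids, (np.random.default_rng(s) for s in seeds[:-1])))
    server_rng = np.random.default_rng(seeds[-1])
    by_id = {ds.profile.center_id: ds for ds in datasets}
    logs = []
    for rnd in range(config.rounds):
        round_losses = {}
        for cid in ids:
            if cid == server_id and not config.server_trains_local:
                continue
            images = by_id[cid].pixels("train")
            labels = by_id[cid].labels("train")
            global_model.set_training(False)
            teacher_probs_logits = []
            with nn.no_grad():
                for lo in range(0, len(images), 32):
                    x = nn.Tensor(_to_nchw(images[lo:lo + 32]))
                    logits, _ = global_model.forward(x)
                    teacher_probs_logits.append(logits.data)
            teacher = np.concatenate(teacher_probs_logits)
            model = local_models[cid]
            opt = nn.SGD(model.parameters(), config.lr)
            model.set_training(True)
            loss_val, nb = 0.0, 0
            for _ in range(config.local_epochs):
                for bidx in _epoch_batches(rngs[cid], len(images),
                                           config.batch_size):
                    x = nn.Tensor(_to_nchw(images[bidx]))
                    logits, _ = model.forward(x)
                    loss = nn.softmax_cross_entropy(logits, labels[bidx])
                    kd = kd_loss_batch(logits, teacher[bidx], temperature)
                    loss = nn.add(loss, nn.scale(kd, lam_kd))
                    opt.zero_grad()
                    loss.backward()
                    opt.step()
                    loss_val += float(loss.data)
                    nb += 1
            model.set_training(False)
            round_losses[cid] = loss_val / nb
        # teacher update on server data (plain CE)
        ds = by_id[server_id]
        images, labels = ds.pixels("train"), ds.labels("train")
        opt = nn.SGD(global_model.parameters(), config.lr)
        global_model.set_training(True)
        for _ in range(config.server_epochs):
            for bidx in _epoch_batches(server_rng, len(images),
                                       config.batch_size):
                x = nn.Tensor(_to_nchw(images[bidx]))
                logits, _ = global_model.forward(x)
                loss = nn.softmax_cross_entropy(logits, labels[bidx])
                opt.zero_grad()
                loss.backward()
                opt.step()
        global_model.set_training(False)
        logs.append(dict(round=rnd, losses=round_losses))
    return global_model, local_models, logs


def run_fedproto_federation(datasets: Sequence[CenterDataset],
                            specs: dict[str, BackboneSpec],
                            config: FederationConfig, mu_proto: float = 0.1
                            ) -> tuple[dict[str, Backbone], PrototypeSet,
                                       list[dict]]:
    """Prototype-sharing federation for heterogeneous local models."""
    config.validate()
    ids = [ds.profile.center_id for ds in datasets]
    local_models = {cid: build_backbone(specs[cid]) for cid in ids}
    seeds = np.random.SeedSequence(config.seed).spawn(len(ids))
    rngs = dict(zip(ids, (np.random.default_rng(s) for s in seeds)))
    by_id = {ds.profile.center_id: ds for ds in datasets}
    global_protos: PrototypeSet | None = None
    logs = []
    for rnd in range(config.rounds):
        round_losses = {}
        client_sets = []
        for cid in ids:
            images = by_id[cid].pixels("train")
            labels = by_id[cid].labels("train")
            model = local_models[cid]
            spec = specs[cid]
            opt = nn.SGD(model.parameters(), config.lr)
            model.set_training(True)
            loss_val, nb = 0.0, 0
            for _ in range(config.local_epochs):
                for bidx in _epoch_batches(rngs[cid], len(images),
                                           config.batch_size):
                    x = nn.Tensor(_to_nchw(images[bidx]))
                    logits, maps = model.forward(x)
                    loss = nn.softmax_cross_entropy(logits, labels[bidx])
                    if global_protos is not None:
                        z = nn.global_avg_pool(maps[spec.tap_stages[-1]])
                        proto = np.stack([global_protos.centroids[int(l)]
                                          for l in labels[bidx]])
                        reg = nn.weighted_channel_mse(
                            nn.sub(z, nn.Tensor(proto)),
                            np.ones(z.shape[1]))
                        loss = nn.add(loss, nn.scale(reg, mu_proto))
                    opt.zero_grad()
                    loss.backward()
                    opt.step()
                    loss_val += float(loss.data)
                    nb += 1
            model.set_training(False)
            round_losses[cid] = loss_val / nb
            emb = _embed(model, images)
            client_sets.append(local_prototypes(emb, labels))
        global_protos = fedproto_round(client_sets)
        logs.append(dict(round=rnd, losses=round_losses))
    return local_models, global_protos, logs
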
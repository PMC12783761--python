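"""Heterogeneous federated learning with robust per-channel feature transfer.

Clients and server run structurally different networks, so parameters are
never averaged.  Knowledge moves through pooled per-channel features at
matched tap stages instead:

* **Client side** — each client trains its personalized local model on local
  cross-entropy plus a transfer loss that pulls its pooled stage features
  toward an affine projection of the frozen global model's features.  The
  per-channel transfer weights are recomputed once per round from the global
  model's projected features on the client's own training data: channel
  relevance is |AUC - 0.5| of the channel against the labels, the top
  ceil(q*C) channels are kept and softmaxed at temperature tau.

* **Server side** — the global model trains on the server center's data with
  cross-entropy plus per-client transfer terms weighted by aggregation
  coefficients alpha_k.  After each round, every client's effect on the
  global model is probed: one gradient step on that client's transfer term
  alone, then the change in cross-entropy on a held-out server batch
  (probe steps are discarded).  alpha_k <- alpha_k * exp(-eta * dCE_k),
  floored at eps and renormalized, so clients whose features hurt the global
  model are gradually filtered out.

Stages are matched by ordinal position among each model's tapped stages, and
projections are affine maps in pooled-channel space owned (and trained) by
the model on the receiving side, initialized near zero so transfer pressure
grows smoothly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import nn
from .backbones import Backbone, BackboneSpec, build_backbone
from .synthetic_cohort import CenterDataset

__all__ = [
    "TransferWeights", "InteractionProjection", "AggregationState",
    "FederationConfig", "RoundLog", "ClientLog",
    "compute_channel_relevance", "make_transfer_weights", "transfer_loss",
    "client_update", "update_aggregation_weights", "server_update",
    "run_federation", "matched_stages", "make_projection",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TransferWeights:
    """Normalized per-channel transfer weights for each interaction stage."""

    per_stage: dict[int, np.ndarray]
    q: float
    tau: float

    def validate(self) -> None:
        if not 0 < self.q <= 1 or self.tau <= 0:
            raise ValueError("need q in (0,1] and tau > 0")
        for s, w in self.per_stage.items():
            if w.min() < 0 or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(f"stage {s}: weights must be a distribution")
            if (w > 0).sum() > math.ceil(self.q * len(w)):
                raise ValueError(f"stage {s}: support exceeds ceil(q*C)")


class InteractionProjection(nn.Module):
    """Per-stage affine maps from source-channel to target-channel space."""

    def __init__(self, rng: np.random.Generator,
                 stage_dims: dict[int, tuple[int, int]], init_sd: float = 0.01):
        self.maps: dict[int, nn.Linear] = {}
        for s, (c_src, c_tgt) in sorted(stage_dims.items()):
            lin = nn.Linear(rng, c_src, c_tgt, zero_init=True)
            # near-zero random init: transfer pressure grows smoothly
            lin.w.data = rng.normal(0.0, init_sd, size=(c_src, c_tgt))
            self.maps[s] = lin

    def parameters(self):
        params = []
        for s in sorted(self.maps):
            params.extend(self.maps[s].parameters())
        return params

    def __call__(self, stage: int, source: nn.Tensor) -> nn.Tensor:
        return self.maps[stage](source)

    def project_values(self, stage: int, source: np.ndarray) -> np.ndarray:
        lin = self.maps[stage]
        return source @ lin.w.data + lin.b.data


@dataclass
class AggregationState:
    """Per-client aggregation weights with their update history."""

    client_ids: list[str]
    alpha: np.ndarray
    eps: float = 0.01
    eta: float = 1.0
    history: list[dict] = field(default_factory=list)

    @classmethod
    def uniform(cls, client_ids: Sequence[str], eps: float = 0.01,
                eta: float = 1.0) -> "AggregationState":
        k = len(client_ids)
        return cls(list(client_ids), np.full(k, 1.0 / k), eps, eta)

    def validate(self) -> None:
        if abs(self.alpha.sum() - 1.0) > 1e-9 or self.alpha.min() < 0:
            raise ValueError("alpha must be a distribution")


@dataclass
class FederationConfig:
    """Hyperparameters of a federation run (all config-exposed)."""

    rounds: int = 20
    local_epochs: int = 1
    server_epochs: int = 1
    lam: float = 0.1            # client transfer strength
    lam_g: float = 0.1          # server transfer strength
    eta: float = 1.0            # aggregation-weight learning rate
    tau: float = 0.05           # transfer-weight softmax temperature
    q: float = 0.5              # fraction of channels transferred
    eps: float = 0.01           # aggregation-weight floor
    batch_size: int = 16
    lr: float = 0.1
    probe_fraction: float = 0.2  # server hold-out used for the dCE probe
    server_trains_local: bool = True
    seed: int = 0

    def validate(self) -> None:
        if min(self.rounds, self.local_epochs, self.server_epochs,
               self.batch_size) < 1:
            raise ValueError("counts must be >= 1")
        if min(self.lam, self.lam_g) < 0:
            raise ValueError("transfer strengths must be >= 0")
        if min(self.eta, self.tau, self.eps, self.lr) <= 0:
            raise ValueError("eta, tau, eps, lr must be positive")
        if not 0 < self.q <= 1:
            raise ValueError("q must lie in (0, 1]")
        if not 0 < self.probe_fraction < 1:
            raise ValueError("probe_fraction must lie in (0, 1)")


@dataclass
class ClientLog:
    client_id: str
    ce_loss: float
    transfer_loss: float


@dataclass
class RoundLog:
    round_idx: int
    clients: list[ClientLog]
    server_ce_before: float
    server_ce_after: float
    delta_ce: dict[str, float]
    alpha: dict[str, float]

    def validate(self) -> None:
        vals = [c.ce_loss for c in self.clients] + \
               [c.transfer_loss for c in self.clients] + \
               [self.server_ce_before, self.server_ce_after]
        if not all(np.isfinite(v) for v in vals) or min(vals) < 0:
            raise ValueError("losses must be finite and >= 0")


# ---------------------------------------------------------------------------
# transfer weights
# ---------------------------------------------------------------------------

def compute_channel_relevance(features: np.ndarray,
                              labels: np.ndarray) -> np.ndarray:
    """Per-channel relevance |AUC_c - 0.5| of channel values vs labels."""
    from sklearn.metrics import roc_auc_score

    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if features.ndim != 2 or len(features) != len(labels):
        raise ValueError("features must be n x C aligned with labels")
    if len(labels) < 4:
        raise ValueError("need n >= 4")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    rel = np.empty(features.shape[1])
    for c in range(features.shape[1]):
        rel[c] = abs(roc_auc_score(labels, features[:, c]) - 0.5)
    return rel


def make_transfer_weights(relevance: np.ndarray, q: float,
                          tau: float) -> np.ndarray:
    """Keep the top ceil(q*C) channels and softmax them at temperature tau.

    Ties break toward the lower channel index; an all-zero relevance vector
    yields uniform weights over the kept set.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if not 0 < q <= 1:
        raise ValueError("q must lie in (0, 1]")
    relevance = np.asarray(relevance, dtype=float)
    if relevance.min() < 0:
        raise ValueError("relevance must be nonnegative")
    c = len(relevance)
    k = math.ceil(q * c)
    # stable sort on (-relevance, index): ties go to the lower index
    order = np.lexsort((np.arange(c), -relevance))
    kept = np.sort(order[:k])
    w = np.zeros(c)
    r = relevance[kept]
    if r.max() == 0.0:
        w[kept] = 1.0 / k
    else:
        z = (r - r.max()) / tau
        e = np.exp(z)
        w[kept] = e / e.sum()
    return w


def transfer_loss(target_features: nn.Tensor, source_features: nn.Tensor,
                  projection: nn.Linear, weights: np.ndarray) -> nn.Tensor:
    """Weighted per-channel squared error between target and projected source.

    L = sum_c w_c * mean_n (target[n,c] - project(source)[n,c])^2.
    """
    proj = projection(source_features)
    if proj.shape != target_features.shape:
        raise ValueError(f"projected source {proj.shape} does not match "
                         f"target {target_features.shape}")
    if len(weights) != target_features.shape[1]:
        raise ValueError("weights must cover the target channels")
    return nn.weighted_channel_mse(nn.sub(target_features, proj), weights)


# ---------------------------------------------------------------------------
# stage matching
# ---------------------------------------------------------------------------

def matched_stages(spec_a: BackboneSpec, spec_b: BackboneSpec
                   ) -> list[tuple[int, int]]:
    """Pair tap stages of two models by ordinal position."""
    k = min(len(spec_a.tap_stages), len(spec_b.tap_stages))
    return [(spec_a.tap_stages[i], spec_b.tap_stages[i]) for i in range(k)]


def make_projection(rng: np.random.Generator, source_spec: BackboneSpec,
                    target_spec: BackboneSpec) -> InteractionProjection:
    """Affine stage projections from source-channel to target-channel space,
    keyed by the target model's stage index."""
    dims = {}
    for s_tgt, s_src in matched_stages(target_spec, source_spec):
        dims[s_tgt] = (source_spec.stage_channels[s_src],
                       target_spec.stage_channels[s_tgt])
    return InteractionProjection(rng, dims)


def _round_transfer_weights(source_feats: dict[int, np.ndarray],
                            projection: InteractionProjection,
                            stage_pairs: list[tuple[int, int]],
                            labels: np.ndarray, q: float, tau: float
                            ) -> TransferWeights:
    """Per-stage weights from projected source features vs local labels.

    Weights live in the target model's channel space, so relevance is
    measured on the source features after projection.
    """
    per_stage = {}
    degenerate = len(np.unique(labels)) < 2 or len(labels) < 4
    for s_tgt, s_src in stage_pairs:
        projected = projection.project_values(s_tgt, source_feats[s_src])
        if degenerate or np.allclose(projected.std(axis=0), 0.0):
            # single-class or constant features: uniform over the kept set
            rel = np.zeros(projected.shape[1])
        else:
            rel = compute_channel_relevance(projected, labels)
        per_stage[s_tgt] = make_transfer_weights(rel, q, tau)
    tw = TransferWeights(per_stage=per_stage, q=q, tau=tau)
    tw.validate()
    return tw


# ---------------------------------------------------------------------------
# client update
# ---------------------------------------------------------------------------

def _epoch_batches(rng: np.random.Generator, n: int, batch_size: int):
    idx = rng.permutation(n)
    for lo in range(0, n, batch_size):
        yield idx[lo:lo + batch_size]


def client_update(local_model: Backbone, global_model: Backbone,
                  images: np.ndarray, labels: np.ndarray,
                  projection: InteractionProjection, config: FederationConfig,
                  rng: np.random.Generator, client_id: str = "?"
                  ) -> ClientLog:
    """One round of personalized local training against the frozen global.

    Minimizes CE + lam * sum_stage transfer_loss for ``local_epochs`` epochs;
    transfer weights are computed once per round from the frozen global
    model's features on this client's training data.  The global model is
    never modified.
    """
    if len(images) == 0:
        raise ValueError("empty client dataset")
    if config.lam < 0:
        raise ValueError("lam must be >= 0")
    labels = np.asarray(labels, dtype=np.int64)
    pairs = matched_stages(local_model.spec, global_model.spec)
    use_transfer = config.lam > 0 and len(pairs) > 0
    if use_transfer:
        global_feats = global_model.stage_features(images)
        weights = _round_transfer_weights(global_feats, projection, pairs,
                                          labels, config.q, config.tau)
    params = local_model.parameters() + \
        (projection.parameters() if use_transfer else [])
    opt = nn.SGD(params, config.lr)
    local_model.set_training(True)
    ce_val = tl_val = 0.0
    n_batches = 0
    for _ in range(config.local_epochs):
        for bidx in _epoch_batches(rng, len(images), config.batch_size):
            x = nn.Tensor(_to_nchw(images[bidx]))
            logits, maps = local_model.forward(x)
            loss = nn.softmax_cross_entropy(logits, labels[bidx])
            ce_val += float(loss.data)
            if use_transfer:
                tl_total = None
                for s_tgt, s_src in pairs:
                    target = nn.global_avg_pool(maps[s_tgt])
                    source = nn.Tensor(global_feats[s_src][bidx])
                    lt = transfer_loss(target, source, projection.maps[s_tgt],
                                       weights.per_stage[s_tgt])
                    tl_total = lt if tl_total is None else nn.add(tl_total, lt)
                tl_val += float(tl_total.data)
                loss = nn.add(loss, nn.scale(tl_total, config.lam))
            opt.zero_grad()
            loss.backward()
            opt.step()
            n_batches += 1
    local_model.set_training(False)
    return ClientLog(client_id=client_id, ce_loss=ce_val / n_batches,
                     transfer_loss=tl_val / max(n_batches, 1))


# ---------------------------------------------------------------------------
# server aggregation
# ---------------------------------------------------------------------------

def update_aggregation_weights(state: AggregationState,
                               delta_ce: np.ndarray) -> AggregationState:
    """Multiplicative-exponential update of the per-client weights.

    alpha_k <- alpha_k * exp(-eta * dCE_k), floored at eps, renormalized.
    A client that raises the global cross-entropy (dCE > 0) loses weight.
    The update is invariant to adding a constant to all dCE values.
    """
    delta_ce = np.asarray(delta_ce, dtype=float)
    if len(delta_ce) != len(state.alpha):
        raise ValueError("one dCE per client required")
    if not np.isfinite(delta_ce).all():
        raise ValueError("dCE must be finite")
    w = state.alpha * np.exp(-state.eta * (delta_ce - delta_ce.mean()))
    w = w / w.sum()
    # exact floor projection: floored entries sit at eps, the rest share 1-m*eps
    for _ in range(len(w)):
        low = w < state.eps
        if not low.any():
            break
        free = ~low
        w[low] = state.eps
        w[free] *= (1.0 - low.sum() * state.eps) / w[free].sum()
    new = AggregationState(state.client_ids, w, state.eps, state.eta,
                           state.history + [dict(
                               delta_ce=delta_ce.tolist(),
                               alpha=w.tolist())])
    new.validate()
    return new


def server_update(global_model: Backbone, local_models: dict[str, Backbone],
                  projections: dict[str, InteractionProjection],
                  images: np.ndarray, labels: np.ndarray,
                  state: AggregationState, config: FederationConfig,
                  rng: np.random.Generator
                  ) -> tuple[np.ndarray, float, float]:
    """One round of dynamic global aggregation.

    Trains the global model on server CE plus alpha-weighted per-client
    transfer terms; afterwards probes each client's marginal effect on a
    held-out server batch (probe steps are discarded) and returns the
    per-client dCE vector plus CE before/after training.
    """
    if len(images) == 0:
        raise ValueError("empty server dataset")
    labels = np.asarray(labels, dtype=np.int64)
    n = len(images)
    n_hold = max(2, int(round(config.probe_fraction * n)))
    # fixed per run: the holdout is the tail of the deterministic order
    hold, fit = np.arange(n - n_hold, n), np.arange(n - n_hold)
    client_ids = state.client_ids
    pairs = {cid: matched_stages(global_model.spec, local_models[cid].spec)
             for cid in client_ids}
    use_transfer = config.lam_g > 0
    feats: dict[str, dict[int, np.ndarray]] = {}
    weights: dict[str, TransferWeights] = {}
    if use_transfer:
        for cid in client_ids:
            feats[cid] = local_models[cid].stage_features(images)
            # server-side weights from global (server) data characteristics
            weights[cid] = _round_transfer_weights(
                feats[cid], projections[cid],
                pairs[cid], labels, config.q, config.tau)

    def server_ce(idx: np.ndarray) -> float:
        probs = global_model.predict_proba(images[idx])
        eps = np.finfo(float).tiny
        return float(-np.log(probs[np.arange(len(idx)), labels[idx]]
                             + eps).mean())

    def transfer_terms(bidx: np.ndarray, maps, only: str | None = None):
        total = None
        for cid in client_ids:
            if only is not None and cid != only:
                continue
            k_term = None
            for s_tgt, s_src in pairs[cid]:
                target = nn.global_avg_pool(maps[s_tgt])
                source = nn.Tensor(feats[cid][s_src][bidx])
                lt = transfer_loss(target, source,
                                   projections[cid].maps[s_tgt],
                                   weights[cid].per_stage[s_tgt])
                k_term = lt if k_term is None else nn.add(k_term, lt)
            if only is None:
                k_term = nn.scale(k_term, float(
                    state.alpha[client_ids.index(cid)]))
            total = k_term if total is None else nn.add(total, k_term)
        return total

    ce_before = server_ce(hold)

    # --- dCE probe per client: one discarded step on its transfer term only
    delta_ce = np.zeros(len(client_ids))
    if use_transfer:
        snapshot = global_model.state()
        proj_snap = {cid: [p.data.copy() for p in projections[cid].parameters()]
                     for cid in client_ids}
        for j, cid in enumerate(client_ids):
            global_model.set_training(True)
            x = nn.Tensor(_to_nchw(images[fit]))
            _, maps = global_model.forward(x)
            probe_loss = nn.scale(transfer_terms(fit, maps, only=cid),
                                  config.lam_g)
            opt = nn.SGD(global_model.parameters()
                         + projections[cid].parameters(), config.lr)
            opt.zero_grad()
            probe_loss.backward()
            opt.step()
            delta_ce[j] = server_ce(hold) - ce_before
            global_model.load_state(snapshot)
            for p, s in zip(projections[cid].parameters(), proj_snap[cid]):
                p.data = s.copy()

    # --- actual server training
    params = global_model.parameters()
    if use_transfer:
        for cid in client_ids:
            params = params + projections[cid].parameters()
    opt = nn.SGD(params, config.lr)
    global_model.set_training(True)
    for _ in range(config.server_epochs):
        for bpos in _epoch_batches(rng, len(fit), config.batch_size):
            bidx = fit[bpos]
            x = nn.Tensor(_to_nchw(images[bidx]))
            logits, maps = global_model.forward(x)
            loss = nn.softmax_cross_entropy(logits, labels[bidx])
            if use_transfer:
                loss = nn.add(loss, nn.scale(
                    transfer_terms(bidx, maps), config.lam_g))
            opt.zero_grad()
            loss.backward()
            opt.step()
    ce_after = server_ce(hold)
    return delta_ce, ce_before, ce_after


# ---------------------------------------------------------------------------
# full federation loop
# ---------------------------------------------------------------------------

def _to_nchw(images: np.ndarray) -> np.ndarray:
    images = np.asarray(images, dtype=nn.DTYPE)
    if images.ndim == 3:
        images = images[..., None]
    return images.transpose(0, 3, 1, 2)


def run_federation(datasets: Sequence[CenterDataset], server_index: int,
                   specs: dict[str, BackboneSpec], config: FederationConfig
                   ) -> tuple[Backbone, dict[str, Backbone], list[RoundLog]]:
    """R rounds of broadcast -> client updates -> server aggregation.

    ``specs`` maps each center_id to its local architecture and must also
    hold a ``"__global__"`` entry for the server's global model.  Returns the
    trained global model, the per-center personalized local models, and one
    RoundLog per round.  Fully deterministic given ``config.seed``.
    """
    config.validate()
    if not 0 <= server_index < len(datasets):
        raise ValueError("server_index out of range")
    if len(datasets) < 2:
        raise ValueError("need at least one client center")
    ids = [ds.profile.center_id for ds in datasets]
    server_id = ids[server_index]
    client_ids = [cid for cid in ids if cid != server_id]

    ss = np.random.SeedSequence(config.seed)
    seeds = ss.spawn(2 * len(ids) + 1)
    global_spec = specs["__global__"]
    global_model = build_backbone(global_spec)
    local_models: dict[str, Backbone] = {}
    proj_client: dict[str, InteractionProjection] = {}
    proj_server: dict[str, InteractionProjection] = {}
    rngs: dict[str, np.random.Generator] = {}
    for i, cid in enumerate(ids):
        spec = specs[cid]
        local_models[cid] = build_backbone(spec)
        rng_i = np.random.default_rng(seeds[2 * i])
        rngs[cid] = np.random.default_rng(seeds[2 * i + 1])
        proj_client[cid] = make_projection(rng_i, global_spec, spec)
        proj_server[cid] = make_projection(rng_i, spec, global_spec)
    server_rng = np.random.default_rng(seeds[-1])

    by_id = {ds.profile.center_id: ds for ds in datasets}
    state = AggregationState.uniform(client_ids, eps=config.eps,
                                     eta=config.eta)
    logs: list[RoundLog] = []
    for rnd in range(config.rounds):
        client_logs = []
        training_ids = list(client_ids)
        if config.server_trains_local:
            training_ids.append(server_id)
        for cid in training_ids:
            ds = by_id[cid]
            try:
                entry = client_update(local_models[cid], global_model,
                                      ds.pixels("train"), ds.labels("train"),
                                      proj_client[cid], config, rngs[cid],
                                      client_id=cid)
            except Exception as exc:
                raise RuntimeError(
                    f"round {rnd}, client {cid}: {exc}") from exc
            client_logs.append(entry)
        ds = by_id[server_id]
        try:
            delta_ce, ce_before, ce_after = server_update(
                global_model, local_models, proj_server,
                ds.pixels("train"), ds.labels("train"), state, config,
                server_rng)
        except Exception as exc:
            raise RuntimeError(f"round {rnd}, server {server_id}: {exc}") \
                from exc
        state = update_aggregation_weights(state, delta_ce)
        log = RoundLog(round_idx=rnd, clients=client_logs,
                       server_ce_before=ce_before, server_ce_after=ce_after,
                       delta_ce=dict(zip(client_ids, delta_ce.tolist())),
                       alpha=dict(zip(client_ids, state.alpha.tolist())))
        log.validate()
        logs.append(log)
    return global_model, local_models, logs
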
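"""Post-federation classification: deep features -> MWU -> mRMR -> SB-ELM.

After federated training, each center's designated network (the personalized
local model for client centers, the global model for the server center —
switchable) turns every patient's ROI into a fixed-length pooled feature
vector.  Features are filtered by a two-sided Mann-Whitney U test, ranked by
the greedy maximum-relevance / minimum-redundancy (mRMR, MID variant)
criterion on 4-bin equal-frequency discretizations, and classified by a
sparse Bayesian extreme learning machine: a fixed random hidden layer whose
output weights carry independent Gaussian ARD priors, fitted by alternating
IRLS (Laplace posterior mode) with evidence-based precision updates and
pruning of irrelevant hidden units.

All selection and fitting happen on training data only; test records are
scored with the frozen chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .backbones import Backbone, extract_features
from .synthetic_cohort import CenterDataset

__all__ = [
    "FeatureTable", "SelectionResult", "SBELMModel",
    "mwu_select", "mrmr_select", "sbelm_fit", "sbelm_predict",
    "feature_table_from_model", "build_center_scores", "fit_chain",
]


@dataclass
class FeatureTable:
    """An n x d matrix of deep features with labels and center ids."""

    values: np.ndarray
    columns: list[str]
    labels: np.ndarray
    center_id: np.ndarray

    def validate(self) -> None:
        if not np.isfinite(self.values).all():
            raise ValueError("feature table contains non-finite entries")
        if self.values.shape != (len(self.labels), len(self.columns)):
            raise ValueError("shape mismatch in feature table")


@dataclass
class SelectionResult:
    """Mann-Whitney p-values/mask plus the greedy mRMR ordering."""

    mwu_pvalues: np.ndarray
    mwu_mask: np.ndarray
    mrmr_order: list[int]
    k: int
    fallback: bool = False      # no feature passed alpha; best-p kept

    def validate(self) -> None:
        if not set(self.mrmr_order) <= set(np.flatnonzero(self.mwu_mask)) \
                and not self.fallback:
            raise ValueError("mRMR picked a feature outside the MWU mask")


# ---------------------------------------------------------------------------
# Mann-Whitney U filtering
# ---------------------------------------------------------------------------

def mwu_select(values: np.ndarray, labels: np.ndarray,
               alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature two-sided Mann-Whitney U p-values and the p < alpha mask.

    Exact enumeration is used when both groups have <= 8 samples, otherwise
    the normal approximation with tie and continuity corrections.  Constant
    features get p = 1.
    """
    from scipy.stats import mannwhitneyu

    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("both classes must be present")
    g0 = values[labels == classes[0]]
    g1 = values[labels == classes[1]]
    method = "exact" if max(len(g0), len(g1)) <= 8 else "asymptotic"
    d = values.shape[1]
    pvals = np.ones(d)
    for j in range(d):
        if np.ptp(values[:, j]) == 0.0:
            continue
        res = mannwhitneyu(g1[:, j], g0[:, j], alternative="two-sided",
                           method=method)
        pvals[j] = min(float(res.pvalue), 1.0)
    return pvals, pvals < alpha


# ---------------------------------------------------------------------------
# mRMR (MID variant)
# ---------------------------------------------------------------------------

def _discretize(col: np.ndarray, bins: int = 4) -> np.ndarray:
    """Equal-frequency binning; duplicate quantile edges collapse."""
    qs = np.quantile(col, np.linspace(0, 1, bins + 1)[1:-1])
    return np.digitize(col, np.unique(qs))


def mrmr_select(values: np.ndarray, labels: np.ndarray, k: int,
                candidates: Sequence[int] | None = None) -> list[int]:
    """Greedy MID selection: argmax I(f;y) - mean_{s in S} I(f;s).

    Mutual information is computed on 4-bin equal-frequency discretizations;
    ties break toward the lower column index.  Returns min(k, #candidates)
    column indices in pick order.
    """
    from sklearn.metrics import mutual_info_score

    if k < 1:
        raise ValueError("k must be >= 1")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if candidates is None:
        candidates = list(range(values.shape[1]))
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate features")
    disc = {j: _discretize(values[:, j]) for j in candidates}
    rel = {j: mutual_info_score(disc[j], labels) for j in candidates}
    selected: list[int] = []
    remaining = list(candidates)
    red_cache: dict[int, float] = {j: 0.0 for j in candidates}
    while remaining and len(selected) < k:
        best_j, best_score = None, -np.inf
        for j in remaining:
            score = rel[j] - (red_cache[j] / len(selected) if selected else 0.0)
            if score > best_score:   # strict: first max wins on ties
                best_j, best_score = j, score
        selected.append(best_j)
        remaining.remove(best_j)
        for j in remaining:
            red_cache[j] += mutual_info_score(disc[j], disc[best_j])
    return selected


# ---------------------------------------------------------------------------
# sparse Bayesian extreme learning machine
# ---------------------------------------------------------------------------

@dataclass
class SBELMModel:
    """Random sigmoid hidden layer with ARD-sparsified logistic output."""

    hidden_w: np.ndarray         # d x h, uniform(-1, 1)
    hidden_b: np.ndarray         # h
    beta: np.ndarray             # coefficients: retained units then bias
    retained: np.ndarray         # indices of surviving hidden units
    alpha_prec: np.ndarray       # ARD precisions of retained units
    means: np.ndarray
    sds: np.ndarray
    converged: bool
    evidence_path: list[float] = field(default_factory=list)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -35, 35)))


def _irls_mode(phi: np.ndarray, y: np.ndarray, a_diag: np.ndarray,
               beta0: np.ndarray, n_iter: int = 30,
               tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mode of penalized logistic regression; returns (beta, W)."""
    beta = beta0.copy()
    for _ in range(n_iter):
        p = _sigmoid(phi @ beta)
        w = np.maximum(p * (1 - p), 1e-10)
        grad = phi.T @ (y - p) - a_diag * beta
        hess = phi.T @ (phi * w[:, None]) + np.diag(a_diag)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    p = _sigmoid(phi @ beta)
    return beta, np.maximum(p * (1 - p), 1e-10)


def sbelm_fit(x: np.ndarray, y: np.ndarray, hidden_n: int = 50,
              seed: int = 0, max_iter: int = 50,
              prune_threshold: float = 1e6) -> SBELMModel:
    """Fit the sparse Bayesian ELM.

    Features are standardized by training means/SDs; hidden weights and
    biases are uniform(-1, 1) from ``seed``.  Output weights follow a
    logistic-link ARD scheme: alternating IRLS for the Laplace posterior
    mode and evidence-based precision updates alpha_i <- gamma_i / beta_i^2
    (gamma_i = 1 - alpha_i * Sigma_ii) until the relative evidence change
    falls below 1e-6 or ``max_iter``; units whose precision exceeds
    ``prune_threshold`` are removed.  The bias column is never pruned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if hidden_n < 2:
        raise ValueError("hidden_n must be >= 2")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    d = x.shape[1]
    means = x.mean(axis=0)
    sds = x.std(axis=0)
    sds[sds == 0] = 1.0
    xs = (x - means) / sds
    hw = rng.uniform(-1, 1, size=(d, hidden_n))
    hb = rng.uniform(-1, 1, size=hidden_n)
    h = _sigmoid(xs @ hw + hb)

    bias_prec = 1e-6
    active = np.arange(hidden_n)
    alpha = np.ones(hidden_n)
    beta = np.zeros(hidden_n + 1)
    evidence_path: list[float] = []
    converged = False
    for _ in range(max_iter):
        phi = np.column_stack([h[:, active], np.ones(len(y))])
        a_diag = np.append(alpha[active], bias_prec)
        beta_act = np.append(beta[:len(active)], beta[-1]) \
            if len(beta) == len(active) + 1 else np.zeros(len(active) + 1)
        beta_act, w = _irls_mode(phi, y, a_diag, beta_act)
        hess = phi.T @ (phi * w[:, None]) + np.diag(a_diag)
        sigma = np.linalg.inv(hess)
        # Laplace evidence over the active set
        p = _sigmoid(phi @ beta_act)
        loglik = float(np.sum(y * np.log(p + 1e-300)
                              + (1 - y) * np.log(1 - p + 1e-300)))
        sign, logdet_h = np.linalg.slogdet(hess)
        evidence = (loglik - 0.5 * float(beta_act @ (a_diag * beta_act))
                    + 0.5 * float(np.sum(np.log(a_diag))) - 0.5 * logdet_h)
        evidence_path.append(evidence)
        # ARD precision update for hidden units (bias stays diffuse)
        gamma = 1.0 - a_diag[:-1] * np.diag(sigma)[:-1]
        with np.errstate(divide="ignore"):
            new_alpha = gamma / np.maximum(beta_act[:-1] ** 2, 1e-300)
        new_alpha = np.clip(new_alpha, 1e-12, 1e12)
        alpha[active] = new_alpha
        keep = new_alpha <= prune_threshold
        if keep.sum() == 0:      # keep the single most confident unit
            keep[np.argmin(new_alpha)] = True
        beta = np.append(beta_act[:-1][keep], beta_act[-1])
        active = active[keep]
        if len(evidence_path) >= 2:
            prev, cur = evidence_path[-2], evidence_path[-1]
            if abs(cur - prev) / max(abs(prev), 1.0) < 1e-6:
                converged = True
                break
    return SBELMModel(hidden_w=hw, hidden_b=hb, beta=beta, retained=active,
                      alpha_prec=alpha[active], means=means, sds=sds,
                      converged=converged, evidence_path=evidence_path)


def sbelm_predict(model: SBELMModel, x: np.ndarray) -> np.ndarray:
    """Probabilities sigmoid(retained-unit linear score); deterministic."""
    x = np.asarray(x, dtype=float)
    if x.shape[1] != len(model.means):
        raise ValueError("feature count differs from training")
    xs = (x - model.means) / model.sds
    h = _sigmoid(xs @ model.hidden_w + model.hidden_b)
    score = h[:, model.retained] @ model.beta[:-1] + model.beta[-1]
    return _sigmoid(score)


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

@dataclass
class ChainModel:
    """Frozen selection + SB-ELM chain fitted on one training table."""

    selection: SelectionResult
    sbelm: SBELMModel

    def predict(self, values: np.ndarray) -> np.ndarray:
        return sbelm_predict(self.sbelm, values[:, self.selection.mrmr_order])


def fit_chain(train_values: np.ndarray, train_labels: np.ndarray,
              alpha: float = 0.05, k: int = 15, hidden_n: int = 50,
              seed: int = 0) -> ChainModel:
    """MWU filter -> mRMR ranking -> SB-ELM fit, train data only."""
    pvals, mask = mwu_select(train_values, train_labels, alpha)
    fallback = False
    if not mask.any():
        mask = pvals == pvals.min()
        fallback = True
    candidates = list(np.flatnonzero(mask))
    order = mrmr_select(train_values, train_labels, k, candidates)
    sel = SelectionResult(mwu_pvalues=pvals, mwu_mask=mask, mrmr_order=order,
                          k=min(k, len(candidates)), fallback=fallback)
    sel.validate()
    sbelm = sbelm_fit(train_values[:, order], train_labels,
                      hidden_n=hidden_n, seed=seed)
    return ChainModel(selection=sel, sbelm=sbelm)


def feature_table_from_model(model: Backbone, images: np.ndarray,
                             labels: np.ndarray,
                             center_id: str) -> FeatureTable:
    bundles = extract_features(model, images)
    mat = np.stack([b.concatenated for b in bundles])
    table = FeatureTable(values=mat,
                         columns=[f"f{i + 1:04d}" for i in range(mat.shape[1])],
                         labels=np.asarray(labels),
                         center_id=np.full(len(labels), center_id))
    table.validate()
    return table


def build_center_scores(global_model: Backbone,
                        local_models: dict[str, Backbone],
                        datasets: Sequence[CenterDataset], server_id: str,
                        alpha: float = 0.05, k: int = 15, hidden_n: int = 50,
                        seed: int = 0, extractor: str = "local",
                        with_train: bool = False):
    """Per-center test probabilities from the federated models.

    For each center: extract train/test features from that center's
    designated model (its personalized local model for clients, the global
    model for the server center when ``extractor='local'``; ``'global'``
    uses the global model everywhere), fit the selection + SB-ELM chain on
    train only, and score the test split.  Returns {center_id: ScoreSet};
    with ``with_train`` a second dict of training-split scores (for cutoff
    selection) is returned as well.
    """
    from .evaluation_stats import ScoreSet

    if extractor not in ("local", "global"):
        raise ValueError("extractor must be 'local' or 'global'")
    out: dict[str, ScoreSet] = {}
    out_train: dict[str, ScoreSet] = {}
    for ds in datasets:
        cid = ds.profile.center_id
        if extractor == "global" or cid == server_id:
            model = global_model
        else:
            if cid not in local_models:
                raise KeyError(f"no local model for center {cid}")
            model = local_models[cid]
        tr = feature_table_from_model(model, ds.pixels("train"),
                                      ds.labels("train"), cid)
        te = feature_table_from_model(model, ds.pixels("test"),
                                      ds.labels("test"), cid)
        chain = fit_chain(tr.values, tr.labels, alpha=alpha, k=k,
                          hidden_n=hidden_n, seed=seed)
        scores = chain.predict(te.values)
        subgroups = _subgroup_tags(ds)
        out[cid] = ScoreSet(scores=scores, labels=te.labels,
                            subgroups=subgroups)
        if with_train:
            out_train[cid] = ScoreSet(scores=chain.predict(tr.values),
                                      labels=tr.labels)
    return (out, out_train) if with_train else out


def _subgroup_tags(ds: CenterDataset) -> dict[str, np.ndarray]:
    ages = np.array([r.age for r in ds.test])
    med = np.median(ages)
    return {
        "age": np.where(ages >= med, "older", "younger"),
        "sex": np.array(["male" if r.sex else "female" for r in ds.test]),
        "smoking": np.array(["yes" if r.smoking else "no" for r in ds.test]),
        "cea": np.array(["pos" if r.cea else "neg" for r in ds.test]),
    }
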
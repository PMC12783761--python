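"""Shared fixtures: tiny cohorts and the 10-seed federation study.

The federation study (heterogeneous pipeline vs FedAvg, plus a label-shuffled
client) is expensive, so it runs once per session and several tests read
from it.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from fedlesion import backbones as bb
from fedlesion import downstream_classifier as dc
from fedlesion import evaluation_stats as ev
from fedlesion import fl_baselines as fb
from fedlesion import hfl_core as hfl
from fedlesion import synthetic_cohort as sc

N_STUDY_SEEDS = 10
STUDY_ROUNDS = 5


def tiny_specs(datasets, seed=0):
    specs = {"__global__": bb.default_spec("tiny_global", seed=seed)}
    for i, ds in enumerate(datasets):
        specs[ds.profile.center_id] = bb.default_spec("tiny_local",
                                                      seed=seed + 100 + i)
    return specs


def shuffle_labels(ds: sc.CenterDataset, seed: int) -> sc.CenterDataset:
    """A poisoned copy of a center: training labels randomly permuted."""
    rng = np.random.default_rng(seed)
    labels = ds.labels("train")
    perm = rng.permutation(labels)
    train = [dataclasses.replace(r, label=int(l))
             for r, l in zip(ds.train, perm)]
    return sc.CenterDataset(profile=ds.profile, train=train,
                            test=list(ds.test))


def mean_test_auc(scores: dict) -> float:
    return float(np.mean([ev.roc_auc_delong(ss).auc
                          for ss in scores.values()]))


@pytest.fixture(scope="session")
def tiny_cohort():
    """One deterministic 4-center desk-scale cohort (40 records/center)."""
    return sc.generate_federation(sc.default_profiles("tiny", base_seed=42))


@pytest.fixture(scope="session")
def federation_study():
    """10-seed comparison of the heterogeneous pipeline vs FedAvg.

    Per seed: a fresh tiny 4-center cohort; (1) heterogeneous federation
    (R=5) and its downstream per-center test AUCs; (2) FedAvg on homogeneous
    clients with the same cohort and its AUCs; (3) a rerun of the
    heterogeneous federation with one label-shuffled ("poisoned") client,
    recording that client's final aggregation weight and per-round dCE.
    """
    results = []
    for s in range(N_STUDY_SEEDS):
        datasets = sc.generate_federation(
            sc.default_profiles("tiny", base_seed=10_000 + 97 * s))
        specs = tiny_specs(datasets, seed=s)
        cfg = hfl.FederationConfig(rounds=STUDY_ROUNDS, seed=s)
        server_id = datasets[0].profile.center_id

        gm, lms, logs = hfl.run_federation(datasets, 0, specs, cfg)
        hflm_scores = dc.build_center_scores(
            gm, lms, datasets, server_id, k=10, hidden_n=40, seed=s)

        fa_model, _ = fb.run_homogeneous_federation(
            "fedavg", datasets, specs["__global__"], cfg)
        fa_scores = dc.build_center_scores(
            fa_model, {}, datasets, server_id, k=10, hidden_n=40, seed=s,
            extractor="global")

        poisoned_id = datasets[-1].profile.center_id
        poisoned = list(datasets[:-1]) + [shuffle_labels(datasets[-1],
                                                         seed=777 + s)]
        _, _, plogs = hfl.run_federation(poisoned, 0, specs, cfg)
        k = len(plogs[-1].alpha)
        results.append(dict(
            seed=s,
            hflm_auc=mean_test_auc(hflm_scores),
            fedavg_auc=mean_test_auc(fa_scores),
            n_rounds=len(logs),
            n_clients_per_round=[len(lg.delta_ce) for lg in logs],
            poisoned_id=poisoned_id,
            poisoned_alpha=plogs[-1].alpha[poisoned_id],
            uniform_alpha=1.0 / k,
            poisoned_dce_rank=[
                float(lg.delta_ce[poisoned_id]
                      > np.median([v for cid, v in lg.delta_ce.items()
                                   if cid != poisoned_id]))
                for lg in plogs],
        ))
    return results
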
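import math

import numpy as np
import pytest

from phideid.corpus import partition_by_patient
from phideid.network import parameter_length
from phideid.training import (
    ServerState,
    SparseUpdate,
    WorkerConfig,
    _epoch_seed,
    dssgd_worker_epoch,
    select_updates,
    server_download,
    server_upload,
    sgd_epoch,
    train_centralized,
    train_dssgd,
    train_local_only,
    train_round_robin,
)


def wcfg(**kw):
    base = dict(theta_d=0.1, theta_u=0.5, gamma=10.0, tau=1e-4, eta=0.9, seed=0)
    base.update(kw)
    return WorkerConfig(**base)


# ---------------------------------------------------------------- sgd


def test_sgd_epoch_eta_zero_is_identity(tiny_params, tiny_docs, tiny_table):
    p2 = sgd_epoch(tiny_params, tiny_docs, 0.0, 1, tiny_table)
    assert np.array_equal(p2.values, tiny_params.values)
    assert p2 is not tiny_params


def test_sgd_epoch_requires_documents(tiny_params, tiny_table):
    with pytest.raises(ValueError):
        sgd_epoch(tiny_params, [], 0.9, 1, tiny_table)


def test_sgd_epoch_deterministic(tiny_params, tiny_docs, tiny_table):
    a = sgd_epoch(tiny_params, tiny_docs, 0.9, 7, tiny_table)
    b = sgd_epoch(tiny_params, tiny_docs, 0.9, 7, tiny_table)
    c = sgd_epoch(tiny_params, tiny_docs, 0.9, 8, tiny_table)
    assert np.array_equal(a.values, b.values)
    assert not np.array_equal(a.values, c.values)


def test_sgd_single_doc_literal_update(tiny_params, tiny_docs, tiny_table):
    from phideid.network import gradient

    doc = tiny_docs[0]
    p2 = sgd_epoch(
        tiny_params, [doc], 0.5, 3, tiny_table, dropout=False, normalize=False
    )
    expected = tiny_params.values - 0.5 * gradient(tiny_params, doc, tiny_table)
    assert np.allclose(p2.values, expected, atol=0)


def test_sgd_normalized_update_divides_by_length(tiny_params, tiny_docs, tiny_table):
    from phideid.network import gradient

    doc = tiny_docs[1]  # 4 tokens
    p2 = sgd_epoch(tiny_params, [doc], 0.8, 3, tiny_table, dropout=False)
    expected = tiny_params.values - 0.8 / len(doc) * gradient(
        tiny_params, doc, tiny_table
    )
    assert np.allclose(p2.values, expected, atol=0)


# ---------------------------------------------------------------- trainers


def test_centralized_zero_epochs(tiny_params, tiny_docs, tiny_table):
    traj = train_centralized(tiny_docs, tiny_params, tiny_table, 0, 0.9, 1)
    assert traj == []


def test_centralized_trajectory_prefix_property(tiny_params, tiny_docs, tiny_table):
    one = train_centralized(tiny_docs, tiny_params, tiny_table, 1, 0.9, 5)
    two = train_centralized(tiny_docs, tiny_params, tiny_table, 2, 0.9, 5)
    assert np.array_equal(one[-1].values, two[0].values)
    assert not np.array_equal(two[0].values, two[1].values)


def test_centralized_epoch_composition(tiny_params, tiny_docs, tiny_table):
    traj = train_centralized(tiny_docs, tiny_params, tiny_table, 2, 0.9, 5)
    p = tiny_params
    for epoch in range(2):
        p = sgd_epoch(p, tiny_docs, 0.9, _epoch_seed(5, epoch, 0), tiny_table)
    assert np.array_equal(traj[-1].values, p.values)


def test_eval_hook_called_once_per_epoch(tiny_params, tiny_docs, tiny_table):
    calls = []
    train_centralized(
        tiny_docs, tiny_params, tiny_table, 3, 0.9, 1,
        eval_hook=lambda w, e, p: calls.append((w, e)),
    )
    assert calls == [(0, 0), (0, 1), (0, 2)]


def test_round_robin_runs_k_local_epochs_per_global_epoch(
    tiny_params, tiny_docs, tiny_table
):
    part = partition_by_patient(tiny_docs, 5, seed=2)
    traj = train_round_robin(part, tiny_params, tiny_table, 1, 0.9, 3)
    p = tiny_params
    for k, subset in enumerate(part.subsets):
        p = sgd_epoch(p, subset, 0.9, _epoch_seed(3, 0, k), tiny_table)
    assert np.array_equal(traj[-1].values, p.values)


def test_round_robin_worker_order_fixed_across_epochs(
    tiny_params, tiny_docs, tiny_table
):
    part = partition_by_patient(tiny_docs, 2, seed=2)
    t1 = train_round_robin(part, tiny_params, tiny_table, 2, 0.9, 4)
    t2 = train_round_robin(part, tiny_params, tiny_table, 2, 0.9, 4)
    assert np.array_equal(t1[-1].values, t2[-1].values)


# ---------------------------------------------------------------- DSSGD ops


def test_select_updates_threshold_clamp_order():
    delta = np.array([0.00005, 15.0, -0.5])
    upd = select_updates(delta, wcfg(theta_u=1.0))
    assert upd.indices.tolist() == [1, 2]
    assert upd.values.tolist() == [10.0, -0.5]
    assert upd.n_clamped == 1


def test_select_updates_all_below_tau_is_empty():
    upd = select_updates(np.full(10, 1e-5), wcfg())
    assert len(upd) == 0


def test_select_updates_cap_counts_full_vector():
    rng = np.random.default_rng(0)
    delta = np.zeros(200)
    delta[rng.choice(200, 100, replace=False)] = 1.0
    upd = select_updates(delta, wcfg(theta_u=0.5, tau=0.0))
    assert len(upd) == 100  # floor(0.5*200) = 100 >= survivors: all kept


def test_select_updates_subsamples_to_cap():
    delta = np.ones(100)
    upd = select_updates(delta, wcfg(theta_u=0.25, tau=0.0))
    assert len(upd) == 25
    assert np.all(np.diff(upd.indices) > 0)
    assert np.all(upd.values == 1.0)
    again = select_updates(delta, wcfg(theta_u=0.25, tau=0.0))
    assert np.array_equal(upd.indices, again.indices)


def test_select_updates_strict_tau():
    delta = np.array([0.1, -0.1, 0.11])
    upd = select_updates(delta, wcfg(tau=0.1, theta_u=1.0))
    assert upd.indices.tolist() == [2]


def test_sparse_update_requires_increasing_indices():
    with pytest.raises(ValueError):
        SparseUpdate(np.array([3, 1]), np.array([0.5, 0.5]))


def make_state(n=10):
    return ServerState(p_glo=np.arange(n, dtype=float), update_counts=np.zeros(n, dtype=np.int64))


def test_server_download_top_counts_with_tie_break():
    state = make_state(3)
    state.update_counts[:] = [5, 0, 3]
    dl = server_download(state, 2 / 3)
    assert dl.indices.tolist() == [0, 2]
    assert dl.values.tolist() == [0.0, 2.0]


def test_server_download_zero_counts_lowest_indices():
    state = make_state(100)
    dl = server_download(state, 0.1)
    assert dl.indices.tolist() == list(range(10))


def test_server_download_full_and_empty():
    state = make_state(7)
    assert server_download(state, 1.0).indices.tolist() == list(range(7))
    assert len(server_download(state, 0.0)) == 0


def test_server_upload_additive_and_counted():
    state = make_state(5)
    server_upload(state, SparseUpdate(np.array([2]), np.array([0.5])))
    server_upload(state, SparseUpdate(np.array([2]), np.array([0.25])))
    assert state.p_glo[2] == 2.75
    assert state.update_counts[2] == 2
    assert state.n_uploads == 2


def test_server_upload_empty_only_bumps_upload_count():
    state = make_state(4)
    before = state.p_glo.copy()
    server_upload(state, SparseUpdate(np.array([], dtype=np.intp), np.array([])))
    assert np.array_equal(state.p_glo, before)
    assert state.n_uploads == 1
    assert state.update_counts.sum() == 0


def test_server_upload_rejects_out_of_range():
    state = make_state(4)
    with pytest.raises(IndexError):
        server_upload(state, SparseUpdate(np.array([9]), np.array([1.0])))


# ---------------------------------------------------------------- DSSGD epoch


def test_worker_epoch_theta_u_zero_uploads_nothing(
    tiny_params, tiny_docs, tiny_table
):
    state = ServerState.initialize(tiny_params)
    before = state.p_glo.copy()
    _, upd = dssgd_worker_epoch(
        tiny_params, state, tiny_docs, wcfg(theta_u=0.0), tiny_table
    )
    assert len(upd) == 0
    assert np.array_equal(state.p_glo, before)


def test_worker_epoch_download_replaces_exact_count(
    tiny_params, tiny_docs, tiny_table
):
    n = len(tiny_params)
    state = ServerState.initialize(tiny_params)
    state.p_glo[:] = 99.0  # make downloaded slots recognizable
    local, _ = dssgd_worker_epoch(
        tiny_params, state, tiny_docs[:1], wcfg(theta_d=0.1, theta_u=0.0, eta=1e-12),
        tiny_table,
    )
    k = math.floor(0.1 * n)
    near_99 = np.isclose(local.values, 99.0, atol=1e-6).sum()
    assert near_99 >= k  # the k downloaded slots hold global values


def test_dssgd_eval_hook_fires_per_worker_per_epoch(
    tiny_params, tiny_docs, tiny_table
):
    part = partition_by_patient(tiny_docs, 5, seed=1)
    calls = []
    train_dssgd(
        part, [wcfg() for _ in range(5)], tiny_params, tiny_table, 3, 42,
        eval_hook=lambda w, e, p: calls.append((w, e)),
    )
    assert len(calls) == 15
    assert sorted(set(calls)) == [(w, e) for w in range(5) for e in range(3)]


def test_dssgd_bitwise_reproducible(tiny_params, tiny_docs, tiny_table):
    part = partition_by_patient(tiny_docs, 2, seed=1)
    cfgs = [wcfg(seed=5), wcfg(seed=5)]
    t1, s1 = train_dssgd(part, cfgs, tiny_params, tiny_table, 2, 9)
    t2, s2 = train_dssgd(part, cfgs, tiny_params, tiny_table, 2, 9)
    for a, b in zip(t1, t2):
        assert np.array_equal(a[-1].values, b[-1].values)
    assert np.array_equal(s1.p_glo, s2.p_glo)
    assert np.array_equal(s1.update_counts, s2.update_counts)


def test_local_only_returns_k_trajectories(tiny_params, tiny_docs, tiny_table):
    part = partition_by_patient(tiny_docs, 3, seed=0)
    trajs = train_local_only(part, tiny_params, tiny_table, 2, 0.9, 1)
    assert len(trajs) == 3
    assert all(len(t) == 2 for t in trajs)
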
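"""Network anatomy, the three operating modes, and the completion oracle."""

import numpy as np
import pytest

from bacon import ModelParams
from bacon.core import kwta
from bacon.hippocampus import (
    LesionConfig,
    build_net,
    create_representation,
    recall_cycle,
    representation_overlap,
    update_representation,
)
from bacon.world import build_ensemble, sample_stream


def _weights_normalized(net):
    """Every cell's potentiated entorhinal weights are equal and sum to one
    (equivalently: the potentiation mask is consistent with its count)."""
    for pmat, cnt in ((net.p_dg, net.cnt_dg), (net.p_ca3, net.cnt_ca3)):
        assert np.array_equal(pmat.sum(axis=0), cnt)
        touched = cnt > 0
        # equal weights 1/m trivially sum to one; check the mask only
        # contains anatomical synapses
    assert np.all(net.p_dg <= net.a_dg)
    assert np.all(net.p_ca3 <= net.a_ca3)


class TestBuildNet:
    def test_afferent_counts_and_determinism(self, tiny_params):
        net = build_net(tiny_params, seed=1)
        assert np.all(net.a_dg.sum(axis=0) == tiny_params.F)
        assert np.all(net.a_ca3.sum(axis=0) == tiny_params.F)
        net2 = build_net(tiny_params, seed=1)
        assert np.array_equal(net.a_dg, net2.a_dg)
        assert not np.array_equal(net.a_dg, net.a_ca3)  # independent draws

    def test_population_afferent_mean_matches_connectivity(self, params):
        # 45 active attributes reach each cell through 45*F/N_Ctx = 2.7
        # anatomical synapses on average
        net = build_net(params, seed=2)
        active = np.arange(45)
        mean = net.a_dg[active].sum(axis=0).mean()
        assert mean == pytest.approx(45 * params.F / params.N_Ctx, rel=0.05)

    def test_impossible_connectivity_rejected(self):
        with pytest.raises(ValueError, match="F <= N_Ctx"):
            ModelParams(N_Ctx=50, N_Gen=10, N_A=20, F=60, Z_0=10,
                        N_Hipp=100, K=20, K_0=5, ThrshCtx=10)


class TestCreation:
    def test_selects_k_dyads_and_potentiates(self, params, rng):
        net = build_net(params, rng=rng)
        ens = build_ensemble(params, 3)
        ctx = ens.add_context(rng=rng)
        active = set(sample_stream(ctx, rng=rng).draw(45))
        rep = create_representation(net, active, rng, context_id=ctx.id)
        assert len(rep.cells) == params.K
        cells = np.fromiter(rep.cells, dtype=np.int64)
        # every winner has at least one potentiated synapse and the
        # winner population is far more innervated than average (~7-8)
        assert np.all(net.cnt_dg[cells] >= 1)
        assert 6 <= net.cnt_dg[cells].mean() <= 9
        _weights_normalized(net)
        # all ordered recurrent pairs among winners exist
        for i in rep.cells:
            assert net.rec_partners[i] == rep.cells - {i}
        # output synapses cover the active attributes for every winner
        assert np.all(net.w_out[np.ix_(cells, sorted(active))])

    def test_identical_inputs_reproduce_winners_up_to_ties(self, small_params):
        # same net, same attributes, different tie-breaking noise: noise
        # only resolves exact ties, so every cell strictly above the KWTA
        # cutoff wins in both creations, and the overlap matches the exact
        # tie analysis (shared tie-group picks are hypergeometric).
        p = small_params
        rng = np.random.default_rng(0)
        net = build_net(p, rng=rng)
        ens = build_ensemble(p, 4)
        ctx = ens.add_context(rng=rng)
        active = set(sample_stream(ctx, rng=rng).draw(45))
        exc = net.a_dg[sorted(active)].sum(axis=0)
        cutoff = np.sort(exc)[::-1][p.K - 1]
        above = np.nonzero(exc > cutoff)[0]
        n_tied = int((exc == cutoff).sum())
        need = p.K - above.size
        r1 = create_representation(net, active, np.random.default_rng(1))
        r2 = create_representation(net, active, np.random.default_rng(2))
        assert set(above) <= r1.cells and set(above) <= r2.cells
        expected = (above.size + need**2 / n_tied) / p.K
        assert representation_overlap(r1, r2) == pytest.approx(expected, abs=0.1)

    def test_encoding_lesion_switches_to_direct_path(self, small_params, rng):
        p = small_params
        net = build_net(p, rng=rng)
        ens = build_ensemble(p, 5)
        ctx = ens.add_context(rng=rng)
        active = set(sample_stream(ctx, rng=rng).draw(60))
        lesioned = create_representation(
            net, active, rng, LesionConfig(dg_off_encoding=True)
        )
        # winners are now the most direct-path-innervated CA3 cells
        exc = net.a_ca3[sorted(active)].sum(axis=0)
        top = set(kwta(exc, p.K, keep_ties=True).tolist())
        assert len(lesioned.cells & top) > 0.8 * p.K
        # and no dentate potentiation occurred
        assert net.cnt_dg.sum() == 0

    def test_plasticity_lesion_keeps_selection_but_blocks_dg(self, small_params):
        p = small_params
        rng1, rng2 = np.random.default_rng(11), np.random.default_rng(11)
        net1, net2 = build_net(p, seed=7), build_net(p, seed=7)
        ens = build_ensemble(p, 6)
        ctx = ens.add_context(seed=8)
        active = set(sample_stream(ctx, seed=9).order[:50].tolist())
        intact = create_representation(net1, active, rng1)
        off = create_representation(
            net2, active, rng2, LesionConfig(dg_plasticity_off=True)
        )
        assert intact.cells == off.cells  # same selection
        assert net2.cnt_dg.sum() == 0  # no dentate potentiation
        assert net2.cnt_ca3.sum() > 0


class TestRecall:
    @pytest.fixture()
    def familiar(self, small_params, rng):
        net = build_net(small_params, rng=rng)
        ens = build_ensemble(small_params, 10)
        ctx = ens.add_context(rng=rng)
        active = set(sample_stream(ctx, rng=rng).draw(45))
        rep = create_representation(net, active, rng, context_id=ctx.id)
        return net, ctx, active, rep

    def test_empty_input(self, familiar, rng):
        net, *_ = familiar
        res = recall_cycle(net, set(), rng=rng)
        assert res.ptrn_o == frozenset() and res.ecout_active == frozenset()

    def test_perfect_probe_completion(self, familiar, rng):
        net, ctx, active, rep = familiar
        res = recall_cycle(net, active, rng=rng)
        assert res.ptrn_fnl == rep.cells
        assert res.active_rep == rep.rep_id
        assert set(active) <= set(res.ecout_active)

    def test_recall_is_read_only(self, familiar, rng):
        net, ctx, active, rep = familiar
        before = (net.p_dg.copy(), net.p_ca3.copy(), net.w_out.copy())
        recall_cycle(net, active, rng=rng)
        assert np.array_equal(net.p_dg, before[0])
        assert np.array_equal(net.p_ca3, before[1])
        assert np.array_equal(net.w_out, before[2])

    def test_subthreshold_probe_extinguishes(self, familiar, rng):
        net, ctx, active, rep = familiar
        probe = set(list(active)[:2])  # too few attributes
        res = recall_cycle(net, probe, rng=rng)
        if res.x_po < net.params.K_0:
            assert res.ptrn_fnl == frozenset()
            assert res.ecout_active == frozenset()

    def test_pattern_size_contracts(self, familiar, rng):
        net, ctx, active, rep = familiar
        for n in (5, 15, 30, 45):
            res = recall_cycle(net, set(list(active)[:n]), rng=rng)
            assert res.x_po <= net.params.K
            assert len(res.ptrn_fnl) == 0 or len(res.ptrn_fnl) >= net.params.K
            if res.ecout_active:
                assert len(res.ptrn_fnl) == net.params.K

    def test_recall_lesion_silences_indirect_path(self, familiar, rng):
        net, ctx, active, rep = familiar
        res = recall_cycle(net, active, LesionConfig(dg_off_recall=True), rng=rng)
        assert res.ptrn_o == frozenset()  # dpf=0: no input at all


class TestCompletionOracle:
    """Brute-force check of recurrent convergence on a reduced network."""

    def _oracle_final(self, net, ptrn_o, p):
        """Independent dense-matrix iterator over the recurrent system."""
        n = p.N_Hipp
        adj = np.zeros((n, n), dtype=bool)
        for rep in net.reps:
            cells = np.fromiter(rep.cells, dtype=np.int64)
            adj[np.ix_(cells, cells)] = True
        np.fill_diagonal(adj, False)
        cur = np.zeros(n, dtype=bool)
        cur[list(ptrn_o)] = True
        for _ in range(p.n_recurrent_iters):
            exc = adj[cur].sum(axis=0)
            pos = exc > 0
            if not pos.any():
                return frozenset()
            if pos.sum() <= p.K:
                cutoff = 1
            else:
                cutoff = np.sort(exc[pos])[::-1][p.K - 1]
            cur = exc >= cutoff
        return frozenset(np.nonzero(cur)[0].tolist())

    def test_convergence_matches_brute_force_and_plurality_wins(self, tiny_params):
        p = tiny_params
        rng = np.random.default_rng(99)
        ens = build_ensemble(p, 42)
        ctx_a = ens.add_context(rng=rng, cid="A")
        ctx_b = ens.add_context((ctx_a, 0.7), rng=rng, cid="B")
        net = build_net(p, rng=rng)
        rep_a = create_representation(net, ctx_a.attrs, rng, context_id="A")
        rep_b = create_representation(net, ctx_b.attrs, rng, context_id="B")
        n_checked = n_plural = 0
        for seed in range(40):
            stream = sample_stream(ctx_a, seed=seed)
            active = set()
            for _ in range(p.N_A):
                active.add(stream.next())
                res = recall_cycle(net, active, rng=np.random.default_rng(seed))
                if res.x_po < p.K_0:
                    assert res.ptrn_fnl == frozenset()
                    continue
                n_checked += 1
                assert res.ptrn_fnl == self._oracle_final(net, res.ptrn_o, p)
                in_a = len(res.ptrn_o & rep_a.cells)
                in_b = len(res.ptrn_o & rep_b.cells)
                only_a = len(res.ptrn_o & (rep_a.cells - rep_b.cells))
                only_b = len(res.ptrn_o & (rep_b.cells - rep_a.cells))
                if in_a > in_b and only_b == 0 and in_a >= p.K_0:
                    n_plural += 1
                    assert res.ptrn_fnl == rep_a.cells
        assert n_checked > 100 and n_plural >= 5  # the oracle actually ran


class TestUpdate:
    def test_idempotent_and_membership_fixed(self, small_params, rng):
        p = small_params
        net = build_net(p, rng=rng)
        ens = build_ensemble(p, 20)
        ctx = ens.add_context(rng=rng)
        sampled = set(sample_stream(ctx, rng=rng).draw(45))
        rep = create_representation(net, sampled, rng)
        before_cells = set(rep.cells)
        snap = (net.p_dg.copy(), net.p_ca3.copy(), net.w_out.copy())
        update_representation(net, rep, sampled, sampled)
        # updating with already-associated attributes changes nothing
        assert np.array_equal(net.p_dg, snap[0])
        assert np.array_equal(net.w_out, snap[2])
        more = set(ctx.attrs)
        update_representation(net, rep, more, sampled)
        assert set(rep.cells) == before_cells
        _weights_normalized(net)

    def test_recalled_count_jumps_to_full_target_set(self, small_params, rng):
        p = small_params
        net = build_net(p, rng=rng)
        ens = build_ensemble(p, 21)
        ctx = ens.add_context(rng=rng)
        sampled = set(sample_stream(ctx, rng=rng).draw(45))
        rep = create_representation(net, sampled, rng)
        target = set(ctx.attrs)
        update_representation(net, rep, target, sampled)
        res = recall_cycle(net, sampled, rng=rng)
        assert res.ptrn_fnl == rep.cells
        assert len(res.ecout_active) == len(target)

    def test_weight_normalization_after_random_sequences(self, tiny_params, rng):
        p = tiny_params
        net = build_net(p, rng=rng)
        ens = build_ensemble(p, 22)
        reps = []
        for i in range(4):
            ctx = ens.add_context(rng=rng)
            active = set(sample_stream(ctx, rng=rng).draw(p.Z_0 + i))
            reps.append((create_representation(net, active, rng), ctx))
        for _ in range(15):
            rep, ctx = reps[rng.integers(len(reps))]
            extra = set(sample_stream(ctx, rng=rng).draw(int(rng.integers(1, p.N_A))))
            update_representation(net, rep, extra, set())
        _weights_normalized(net)


class TestOverlap:
    def test_identity_and_disjoint(self, tiny_params, rng):
        net = build_net(tiny_params, rng=rng)
        ens = build_ensemble(tiny_params, 23)
        ctx = ens.add_context(rng=rng)
        rep = create_representation(net, ctx.attrs, rng)
        assert representation_overlap(rep, rep) == 1.0
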
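"""Scoring decomposition, Monte Carlo behavior, superposition and ensemble analysis."""

import math

import numpy as np
import pytest

from xlmstruct.core import CrossLink, ResidueRef
from xlmstruct.errors import RepresentationError
from xlmstruct.modeling import (
    CONSISTENT,
    SINGLE,
    MCState,
    Model,
    Representation,
    RepresentationConfig,
    RestraintSet,
    SamplerConfig,
    Scorer,
    ScoringParams,
    build_representation,
    cluster_solutions,
    crosslink_log_likelihood,
    forward_model_probability,
    kabsch_superpose,
    localization_density,
    mc_step,
    metropolis_accept,
    precision_accuracy,
    prior_score,
    replica_exchange_sample,
    rmsd,
    satisfaction_report,
    select_best,
    superpose_core,
    total_score,
)
from xlmstruct.struct import StructureModel


def tiny_rep(seed=0, n_strings=1):
    """Two 4-bead rigid bodies plus a flexible 3-bead linker."""
    rng = np.random.default_rng(seed)
    residues = np.arange(1, 12)
    # a relaxed chain path: consecutive beads 4 Å apart, bodies well separated
    positions = np.array(
        [
            [0, 0, 0], [4, 0, 0], [4, 4, 0], [0, 4, 0],  # core
            [0, 8, 0], [0, 12, 0], [0, 16, 0],  # flexible string
            [0, 20, 0], [4, 20, 0], [4, 24, 0], [0, 24, 0],  # mobile
        ],
        dtype=float,
    )
    positions += rng.normal(scale=0.01, size=positions.shape)
    return Representation(
        residues=residues,
        radii=np.where((residues >= 5) & (residues <= 7), 3.0, 2.4),
        positions0=positions,
        bodies=[np.arange(0, 4), np.arange(7, 11)],
        body_names=["core", "mobile"],
        strings=[np.arange(4, 7)],
        core_body=0,
        chains=[(1, 11)],
    )


def restraints_for(rep, pairs=((2, 9, CONSISTENT), (3, 10, SINGLE)), threshold=35.0):
    links = [
        (CrossLink(ResidueRef(a), ResidueRef(b)), cls) for a, b, cls in pairs
    ]
    return RestraintSet(crosslinks=links, disulfides=[(1, 8)], satisfaction_threshold=threshold)


PSI = {"consistent": 0.05, "single": 0.2}


class TestForwardModel:
    @pytest.mark.parametrize("form", ["logistic", "step"])
    def test_half_at_inflection(self, form):
        p = ScoringParams(forward_d0=20.0, forward_form=form)
        assert forward_model_probability(20.0, p) == pytest.approx(0.5)

    def test_contact_near_one_far_near_zero(self):
        p = ScoringParams(forward_d0=35.0, forward_lambda=2.0)
        assert forward_model_probability(0.0, p) > 0.99
        assert forward_model_probability(200.0, p) < 1e-6

    def test_monotone_nonincreasing(self):
        p = ScoringParams()
        d = np.linspace(0, 100, 400)
        f = forward_model_probability(d, p)
        assert np.all(np.diff(f) <= 1e-12)


class TestScoreComponents:
    def test_loglik_zero_when_links_satisfied_and_psi_small(self):
        rep = tiny_rep()
        rs = restraints_for(rep)
        pos = rep.positions0.copy()
        psi = {"consistent": 1e-9, "single": 1e-9}
        # all restrained pairs are well under d0=35 at the initial layout
        ll = crosslink_log_likelihood(pos, rep, rs, psi)
        assert ll == pytest.approx(0.0, abs=5e-3)

    def test_link_at_inflection_is_log_half_regardless_of_psi(self):
        rep = tiny_rep()
        rs = RestraintSet(
            crosslinks=[(CrossLink(ResidueRef(1), ResidueRef(8)), CONSISTENT)],
            disulfides=[],
        )
        pos = rep.positions0.copy()
        pos[7] = pos[0] + [35.0, 0, 0]
        p = ScoringParams(forward_d0=35.0)
        for psi_c in (0.01, 0.2, 0.45):
            ll = crosslink_log_likelihood(
                pos, rep, rs, {"consistent": psi_c, "single": 0.1}, p
            )
            assert ll == pytest.approx(math.log(0.5), abs=1e-9)

    def test_loglik_matches_per_link_brute_force(self, rng):
        rep = tiny_rep()
        rs = restraints_for(rep)
        pos = rep.positions0 + rng.normal(0, 10, rep.positions0.shape)
        p = ScoringParams()
        expected = 0.0
        for ln, cls in rs.crosslinks:
            i = rep.bead_index(ln.a.position)
            j = rep.bead_index(ln.b.position)
            d = np.linalg.norm(pos[i] - pos[j])
            f = 1.0 / (1.0 + math.exp((d - p.forward_d0) / p.forward_lambda))
            psi = PSI[cls]
            expected += math.log(psi + (1 - 2 * psi) * f)
        assert crosslink_log_likelihood(pos, rep, rs, PSI, p) == pytest.approx(expected)

    def test_prior_zero_for_relaxed_configuration(self):
        rep = tiny_rep()
        rs = RestraintSet(crosslinks=[], disulfides=[])
        assert prior_score(rep.positions0, rep, rs) == pytest.approx(0.0, abs=0.1)

    def test_full_overlap_penalty(self):
        rep = tiny_rep()
        rs = RestraintSet(crosslinks=[], disulfides=[])
        pos = rep.positions0.copy()
        pos[7] = pos[0]  # bead 8 (mobile, r=2.4) onto bead 1 (core, r=2.4)
        p = ScoringParams()
        expected = p.k_excluded * (2.4 + 2.4) ** 2
        base = prior_score(rep.positions0, rep, rs, p)
        assert prior_score(pos, rep, rs, p) - base >= expected - 5.0

    def test_prior_matches_brute_force_oracle(self, rng):
        rep = tiny_rep()
        rs = restraints_for(rep)
        p = ScoringParams()
        pos = rep.positions0 + rng.normal(0, 4, rep.positions0.shape)
        # independent O(n^2) evaluation
        ev = 0.0
        for i in range(rep.n_beads):
            for j in range(i + 1, rep.n_beads):
                if rep.body_id[i] == rep.body_id[j]:
                    continue
                if abs(int(rep.residues[i]) - int(rep.residues[j])) <= p.ev_min_separation:
                    continue
                d = np.linalg.norm(pos[i] - pos[j])
                ev += p.k_excluded * max(0.0, rep.radii[i] + rep.radii[j] - d) ** 2
        conn = 0.0
        for i in range(rep.n_beads - 1):
            d = np.linalg.norm(pos[i] - pos[i + 1])
            conn += p.k_connect * max(0.0, d - p.connect_rest_per_gap) ** 2
        ss = 0.0
        for a, b in rs.disulfides:
            d = np.linalg.norm(pos[rep.bead_index(a)] - pos[rep.bead_index(b)])
            ss += p.k_disulfide * (d - p.disulfide_rest) ** 2
        assert prior_score(pos, rep, rs, p) == pytest.approx(ev + conn + ss, rel=1e-9)

    def test_total_score_is_component_sum(self, rng):
        rep = tiny_rep()
        rs = restraints_for(rep)
        pos = rep.positions0 + rng.normal(0, 5, rep.positions0.shape)
        total = total_score(pos, rep, rs, PSI)
        parts = -crosslink_log_likelihood(pos, rep, rs, PSI) + prior_score(pos, rep, rs)
        assert total == pytest.approx(parts, rel=1e-12)

    def test_moving_violated_link_below_d0_decreases_score(self):
        rep = tiny_rep()
        rs = RestraintSet(
            crosslinks=[(CrossLink(ResidueRef(1), ResidueRef(8)), CONSISTENT)],
            disulfides=[],
        )
        far = rep.positions0.copy()
        far[rep.bodies[1]] += [100.0, 0, 0]
        near = rep.positions0.copy()
        near[rep.bodies[1]] += [10.0, 0, 0]
        assert total_score(near, rep, rs, PSI) < total_score(far, rep, rs, PSI)


class TestRepresentationInvariants:
    def test_partition_enforced(self):
        with pytest.raises(RepresentationError):
            Representation(
                residues=np.arange(1, 5),
                radii=np.full(4, 2.4),
                positions0=np.zeros((4, 3)),
                bodies=[np.array([0, 1])],
                body_names=["a"],
                strings=[np.array([1, 2, 3])],  # bead 1 claimed twice
                core_body=0,
                chains=[(1, 4)],
            )

    def test_build_from_structure(self):
        coords = {i: (np.array([3.8 * i, 0.0, 0.0]), "K") for i in range(1, 21)}
        s = StructureModel("toy", {"A": coords})
        cfg = RepresentationConfig(
            protein_id="toy",
            chains=[(1, 24)],
            rigid_bodies={"N": [(1, 8)], "C": [(13, 20)]},
            flexible={},
            core="N",
        )
        rep = build_representation(s, cfg)
        assert len(rep.bodies) == 2
        assert len(rep.strings) == 2  # 9-12 linker and 21-24 tail
        total = sum(len(g) for g in rep.bodies) + sum(len(g) for g in rep.strings)
        assert total == rep.n_beads == 24
        assert rep.body_names[rep.core_body] == "N"

    def test_config_residue_outside_chain_rejected(self):
        s = StructureModel("toy", {"A": {1: (np.zeros(3), "K")}})
        cfg = RepresentationConfig(
            protein_id="toy",
            chains=[(1, 10)],
            rigid_bodies={"N": [(5, 15)]},
            flexible={},
            core="N",
        )
        with pytest.raises(RepresentationError):
            build_representation(s, cfg)


class TestMonteCarlo:
    def test_downhill_always_accepted(self, rng):
        assert metropolis_accept(-5.0, 1.0, rng)
        assert metropolis_accept(0.0, 1.0, rng)

    def test_uphill_acceptance_rate_matches_boltzmann_factor(self):
        rng = np.random.default_rng(5)
        delta, T = 1.2, 1.7
        accepted = sum(metropolis_accept(delta, T, rng) for _ in range(40_000))
        assert accepted / 40_000 == pytest.approx(math.exp(-delta / T), abs=0.01)

    def test_fixed_seed_trajectory_reproducible(self):
        rep = tiny_rep()
        scorer = Scorer(rep, restraints_for(rep))
        cfg = SamplerConfig(seed=3)

        def run():
            rng = np.random.default_rng(42)
            psi = np.array([0.05, 0.2])
            st = MCState(rep.positions0.copy(), psi, scorer.total(rep.positions0, psi))
            for _ in range(300):
                st, _ = mc_step(st, scorer, cfg, rng)
            return st

        a, b = run(), run()
        assert np.array_equal(a.positions, b.positions)
        assert a.score == b.score

    def test_rigid_moves_preserve_intra_body_distances(self):
        rep = tiny_rep()
        scorer = Scorer(rep, restraints_for(rep))
        cfg = SamplerConfig(seed=0, max_rotate=0.5)
        rng = np.random.default_rng(7)
        psi = np.array([0.05, 0.2])
        st = MCState(rep.positions0.copy(), psi, scorer.total(rep.positions0, psi))
        body = rep.bodies[1]
        ref = rep.positions0[body]
        ref_d = np.linalg.norm(ref[:, None] - ref[None, :], axis=-1)
        for _ in range(500):
            st, _ = mc_step(st, scorer, cfg, rng)
            cur = st.positions[body]
            cur_d = np.linalg.norm(cur[:, None] - cur[None, :], axis=-1)
            assert np.max(np.abs(cur_d - ref_d)) < 1e-9

    def test_core_body_never_moves_and_psi_stays_bounded(self):
        rep = tiny_rep()
        scorer = Scorer(rep, restraints_for(rep))
        cfg = SamplerConfig(seed=0)
        rng = np.random.default_rng(11)
        psi = np.array([0.05, 0.2])
        st = MCState(rep.positions0.copy(), psi, scorer.total(rep.positions0, psi))
        for _ in range(500):
            st, _ = mc_step(st, scorer, cfg, rng)
        assert np.array_equal(st.positions[rep.bodies[0]], rep.positions0[rep.bodies[0]])
        assert np.all(st.psi >= scorer.params.psi_min)
        assert np.all(st.psi <= scorer.params.psi_max)

    def test_incremental_score_matches_full_recompute(self):
        rep = tiny_rep()
        scorer = Scorer(rep, restraints_for(rep))
        cfg = SamplerConfig(seed=0)
        rng = np.random.default_rng(13)
        psi = np.array([0.05, 0.2])
        st = MCState(rep.positions0.copy(), psi, scorer.total(rep.positions0, psi))
        for _ in range(800):
            st, _ = mc_step(st, scorer, cfg, rng, temperature=2.0)
        assert st.score == pytest.approx(scorer.total(st.positions, st.psi), abs=1e-8)

    def test_two_state_metropolis_converges_to_boltzmann(self):
        """Discrete two-state score surface: frequencies approach e^{-ΔS/T}."""
        rng = np.random.default_rng(2024)
        scores = {0: 0.0, 1: 1.0}
        state, counts = 0, [0, 0]
        for _ in range(100_000):
            proposal = 1 - state
            if metropolis_accept(scores[proposal] - scores[state], 1.0, rng):
                state = proposal
            counts[state] += 1
        ratio = counts[1] / counts[0]
        assert ratio == pytest.approx(math.exp(-1.0), rel=0.05)


class TestReplicaExchange:
    def test_identical_temperatures_accept_all_swaps(self):
        rep = tiny_rep()
        rs = restraints_for(rep)
        cfg = SamplerConfig(
            n_replicas=4,
            temperature_min=1.0,
            temperature_max=1.0,
            n_models_total=40,
            steps_per_model=2,
            seed=1,
        )
        ens = replica_exchange_sample(rep, rs, cfg)
        assert ens.swap_rate == 1.0

    def test_single_replica_runs_plain_metropolis(self):
        rep = tiny_rep()
        rs = restraints_for(rep)
        cfg = SamplerConfig(n_replicas=1, n_models_total=50, steps_per_model=2, seed=1)
        ens = replica_exchange_sample(rep, rs, cfg)
        assert len(ens.models) == 50

    def test_same_seed_same_ensemble(self):
        rep = tiny_rep()
        rs = restraints_for(rep)
        cfg = SamplerConfig(n_replicas=2, n_models_total=30, steps_per_model=2, seed=9)
        e1 = replica_exchange_sample(rep, rs, cfg)
        e2 = replica_exchange_sample(rep, rs, cfg)
        assert np.array_equal(e1.scores(), e2.scores())

    def test_runs_are_labelled(self):
        rep = tiny_rep()
        rs = restraints_for(rep)
        cfg = SamplerConfig(
            n_replicas=2, n_models_total=20, n_runs=2, steps_per_model=2, seed=9
        )
        ens = replica_exchange_sample(rep, rs, cfg)
        assert {m.run for m in ens.models} == {0, 1}


class TestSelectBest:
    def models(self, scores):
        return [Model(np.zeros((1, 3)), np.zeros(2), s, index=i) for i, s in enumerate(scores)]

    def test_full_selection_is_identity(self):
        rep = tiny_rep()
        from xlmstruct.modeling import Ensemble

        ens = Ensemble(self.models([3.0, 1.0, 2.0]), rep)
        assert [m.score for m in select_best(ens, 3)] == [1.0, 2.0, 3.0]

    def test_n1_is_argmin(self):
        from xlmstruct.modeling import Ensemble

        ens = Ensemble(self.models([3.0, 1.0, 2.0]), tiny_rep())
        assert select_best(ens, 1)[0].score == 1.0

    def test_ties_broken_by_recording_order(self):
        from xlmstruct.modeling import Ensemble

        ens = Ensemble(self.models([2.0, 1.0, 1.0]), tiny_rep())
        picked = select_best(ens, 2)
        assert [m.index for m in picked] == [1, 2]

    def test_oversized_request_rejected(self):
        from xlmstruct.modeling import Ensemble

        ens = Ensemble(self.models([1.0]), tiny_rep())
        with pytest.raises(ValueError):
            select_best(ens, 2)


class TestSuperposition:
    def test_identity(self):
        rep = tiny_rep()
        moved, core_rmsd = superpose_core(
            rep.positions0, rep.positions0, rep.core_indices
        )
        assert core_rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(moved, rep.positions0)

    def test_known_rotation_recovered(self, rng):
        rep = tiny_rep()
        theta = 0.7
        R = np.array(
            [
                [math.cos(theta), -math.sin(theta), 0],
                [math.sin(theta), math.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        rotated = rep.positions0 @ R.T + [5, -3, 2]
        moved, core_rmsd = superpose_core(rotated, rep.positions0, rep.core_indices)
        assert core_rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(moved, rep.positions0, atol=1e-8)

    def test_matches_quaternion_oracle(self, rng):
        """Kabsch (SVD) against an independent Horn quaternion superposition."""
        mobile = rng.normal(0, 10, (12, 3))
        reference = rng.normal(0, 10, (12, 3))
        R, t = kabsch_superpose(mobile, reference)
        fitted = mobile @ R.T + t

        # Horn's closed-form quaternion method
        mc, rc = mobile.mean(0), reference.mean(0)
        a, b = mobile - mc, reference - rc
        S = a.T @ b
        N = np.array(
            [
                [S[0, 0] + S[1, 1] + S[2, 2], S[1, 2] - S[2, 1], S[2, 0] - S[0, 2], S[0, 1] - S[1, 0]],
                [S[1, 2] - S[2, 1], S[0, 0] - S[1, 1] - S[2, 2], S[0, 1] + S[1, 0], S[2, 0] + S[0, 2]],
                [S[2, 0] - S[0, 2], S[0, 1] + S[1, 0], -S[0, 0] + S[1, 1] - S[2, 2], S[1, 2] + S[2, 1]],
                [S[0, 1] - S[1, 0], S[2, 0] + S[0, 2], S[1, 2] + S[2, 1], -S[0, 0] - S[1, 1] + S[2, 2]],
            ]
        )
        w, v = np.linalg.eigh(N)
        q = v[:, np.argmax(w)]
        q0, q1, q2, q3 = q
        Rq = np.array(
            [
                [q0**2 + q1**2 - q2**2 - q3**2, 2 * (q1 * q2 - q0 * q3), 2 * (q1 * q3 + q0 * q2)],
                [2 * (q1 * q2 + q0 * q3), q0**2 - q1**2 + q2**2 - q3**2, 2 * (q2 * q3 - q0 * q1)],
                [2 * (q1 * q3 - q0 * q2), 2 * (q2 * q3 + q0 * q1), q0**2 - q1**2 - q2**2 + q3**2],
            ]
        )
        fitted_q = a @ Rq.T + rc
        assert rmsd(fitted, reference) == pytest.approx(rmsd(fitted_q, reference), abs=1e-9)


class TestEnsembleAnalysis:
    def two_cluster_models(self, rep, n=10, offset=40.0):
        models = []
        for i in range(n):
            pos = rep.positions0.copy()
            if i % 2:
                pos[rep.bodies[1]] += [0.0, offset, 0.0]
            models.append(Model(pos, np.zeros(2), float(i)))
        return models

    def test_two_planted_configurations_separate_perfectly(self):
        rep = tiny_rep()
        models = self.two_cluster_models(rep)
        res = cluster_solutions(models, 2, rep, seed=0)
        labels = res.assignments
        assert len(set(labels[::2])) == 1 and len(set(labels[1::2])) == 1
        assert labels[0] != labels[1]

    def test_k1_single_cluster(self):
        rep = tiny_rep()
        models = self.two_cluster_models(rep)
        res = cluster_solutions(models, 1, rep, seed=0)
        assert set(res.assignments) == {0}
        assert len(res.members[0]) == len(models)

    def test_duplicate_solutions_zero_precision(self):
        rep = tiny_rep()
        models = [Model(rep.positions0.copy(), np.zeros(2), 0.0) for _ in range(5)]
        res = cluster_solutions(models, 1, rep, seed=0)
        center = models[res.center_indices[0]]
        pa = precision_accuracy(models, center, rep)
        assert pa["precision"] == pytest.approx(0.0, abs=1e-9)

    def test_displaced_domain_contributes_its_offset(self):
        rep = tiny_rep()
        center = Model(rep.positions0.copy(), np.zeros(2), 0.0)
        moved = rep.positions0.copy()
        t = 7.0
        moved[rep.bodies[1]] += [0, 0, t]
        member = Model(moved, np.zeros(2), 1.0)
        pa = precision_accuracy(
            [member], center, rep, domains={"mobile": rep.bodies[1]}
        )
        assert pa["per_domain_precision"]["mobile"] == pytest.approx(t, abs=1e-6)

    def test_accuracy_against_reference(self):
        rep = tiny_rep()
        center = Model(rep.positions0.copy(), np.zeros(2), 0.0)
        pa = precision_accuracy([center], center, rep, reference=rep.positions0)
        assert pa["accuracy"] == pytest.approx(0.0, abs=1e-9)

    def test_empty_cluster_rejected(self):
        rep = tiny_rep()
        with pytest.raises(ValueError):
            precision_accuracy([], Model(rep.positions0, np.zeros(2), 0.0), rep)


class TestLocalizationDensity:
    def test_single_model_is_binary(self):
        rep = tiny_rep()
        m = Model(rep.positions0.copy(), np.zeros(2), 0.0)
        grid = localization_density([m], rep.bodies[1], rep, voxel_size=2.0)
        vals = np.unique(grid.values)
        assert set(vals).issubset({0.0, 1.0})
        assert grid.values.max() == 1.0

    def test_identical_members_match_single_model(self):
        rep = tiny_rep()
        m = Model(rep.positions0.copy(), np.zeros(2), 0.0)
        g1 = localization_density([m], rep.bodies[1], rep, voxel_size=2.0)
        g5 = localization_density([m] * 5, rep.bodies[1], rep, voxel_size=2.0)
        assert np.array_equal(g1.values, g5.values)

    def test_disjoint_halves_cap_at_half(self):
        rep = tiny_rep()
        far = rep.positions0.copy()
        far[rep.bodies[1]] += [0, 200.0, 0]
        models = [Model(rep.positions0.copy(), np.zeros(2), 0.0), Model(far, np.zeros(2), 0.0)]
        grid = localization_density(models, rep.bodies[1], rep, voxel_size=3.0)
        assert grid.values.max() == pytest.approx(0.5)

    def test_order_invariant_and_bounded(self):
        rep = tiny_rep()
        far = rep.positions0.copy()
        far[rep.bodies[1]] += [0, 30.0, 0]
        a = Model(rep.positions0.copy(), np.zeros(2), 0.0)
        b = Model(far, np.zeros(2), 0.0)
        g_ab = localization_density([a, b], rep.bodies[1], rep, voxel_size=3.0)
        g_ba = localization_density([b, a], rep.bodies[1], rep, voxel_size=3.0)
        assert np.array_equal(g_ab.values, g_ba.values)
        assert g_ab.values.min() >= 0.0 and g_ab.values.max() <= 1.0

    def test_ccp4_roundtrip(self, tmp_path):
        import gemmi

        rep = tiny_rep()
        m = Model(rep.positions0.copy(), np.zeros(2), 0.0)
        grid = localization_density([m], rep.bodies[1], rep, voxel_size=3.0)
        path = tmp_path / "density.ccp4"
        grid.write_ccp4(path)
        back = gemmi.read_ccp4_map(str(path))
        assert np.allclose(np.asarray(back.grid), grid.values.astype(np.float32))


class TestSatisfactionReport:
    def test_all_under_threshold_fully_satisfied(self):
        rep = tiny_rep()
        rs = restraints_for(rep, threshold=100.0)
        models = [Model(rep.positions0.copy(), np.zeros(2), 0.0)]
        rpt = satisfaction_report(models, rep, rs)
        assert rpt.fraction_satisfied == 1.0

    def test_tiny_threshold_none_satisfied(self):
        rep = tiny_rep()
        rs = restraints_for(rep, threshold=1e-6)
        models = [Model(rep.positions0.copy(), np.zeros(2), 0.0)]
        rpt = satisfaction_report(models, rep, rs)
        assert rpt.fraction_satisfied == 0.0

    def test_satisfied_in_any_member_counts(self):
        rep = tiny_rep()
        rs = RestraintSet(
            crosslinks=[(CrossLink(ResidueRef(2), ResidueRef(9)), CONSISTENT)],
            disulfides=[],
            satisfaction_threshold=30.0,
        )
        near = Model(rep.positions0.copy(), np.zeros(2), 0.0)
        far_pos = rep.positions0.copy()
        far_pos[rep.bodies[1]] += [100, 0, 0]
        far = Model(far_pos, np.zeros(2), 0.0)
        rpt_far_only = satisfaction_report([far], rep, rs)
        rpt_both = satisfaction_report([far, near], rep, rs, center=far)
        assert rpt_far_only.fraction_satisfied == 0.0
        assert rpt_both.fraction_satisfied == 1.0
        assert rpt_both.per_link[0].satisfied_in_center is False

    def test_contact_map_symmetric_bounded(self):
        rep = tiny_rep()
        rs = restraints_for(rep)
        models = [Model(rep.positions0.copy(), np.zeros(2), 0.0)]
        rpt = satisfaction_report(models, rep, rs, contact_cutoff=10.0)
        cm = rpt.contact_map
        assert np.array_equal(cm, cm.T)
        assert cm.min() >= 0 and cm.max() <= 1
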
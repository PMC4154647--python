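"""Reaction coordinates, state/stage assignment, WHAM and passage times."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import logsumexp

from dualbasin import analysis as ana
from dualbasin.analysis import (
    StateThresholds,
    assign_conformation,
    assign_stage,
    compute_frames,
    cutoff_contact_profile,
    energy_stage_stats,
    fraction_native_contacts,
    free_energy_profile,
    mean_passage_time,
    population_table,
    reweighted_populations,
    wham_offsets,
    wham_weights,
)
from dualbasin.energy import EnergyBreakdown
from dualbasin.simulate import FirstPassageRecord


class TestFractionNativeContacts:
    def test_native_coordinates_give_one(self, toy_complex):
        t = toy_complex.topology
        frames = compute_frames(t.ref_positions_B, t)
        assert frames[0].q_idna == 1.0

    def test_separated_chains_give_zero(self, toy_complex):
        t = toy_complex.topology
        x = t.ref_positions_B.copy()
        x[t.protein_mask] += 1e4
        frames = compute_frames(x, t)
        assert frames[0].q_idna == 0.0
        assert frames[0].cutoff_contact_count == 0

    def test_half_displaced_pairs_give_half(self):
        pos = np.zeros((8, 3))
        idx = np.array([[0, 1], [2, 3], [4, 5], [6, 7]])
        r0 = np.full(4, 5.0)
        pos[1] = [5.0, 0, 0]
        pos[3] = [5.5, 0, 0]   # formed: 5.5 < 1.2*5
        pos[5] = [9.0, 0, 0]   # broken
        pos[7] = [50.0, 0, 0]  # broken
        assert fraction_native_contacts(pos, idx, r0) == 0.5

    def test_empty_subset_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            fraction_native_contacts(np.zeros((2, 3)), np.empty((0, 2)), np.empty(0))

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.floats(1.0, 5.0))
    def test_uniform_expansion_never_increases_q(self, scale):
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 10, (12, 3))
        idx = np.array([[i, i + 6] for i in range(6)])
        r0 = np.linalg.norm(pos[idx[:, 1]] - pos[idx[:, 0]], axis=-1) * \
            rng.uniform(0.8, 1.3, 6)
        q1 = fraction_native_contacts(pos, idx, r0)
        q2 = fraction_native_contacts(pos * scale, idx, r0)
        assert q2 <= q1


class TestStateAssignment:
    def test_apo_like_state(self):
        assert assign_conformation(0.9, 0.0) == "A"

    def test_intermediate_state(self):
        assert assign_conformation(0.05, 0.05) == "I"

    def test_bound_like_state(self):
        assert assign_conformation(0.0, 0.95) == "B"

    def test_middle_ground_is_unassigned(self):
        assert assign_conformation(0.5, 0.5) == "UNASSIGNED"

    def test_zero_tolerance_operationalizes_exact_zero(self):
        thr = StateThresholds(zero_tol=0.05)
        assert assign_conformation(0.9, 0.04, thr) == "A"
        assert assign_conformation(0.9, 0.2, thr) == "UNASSIGNED"

    def test_invalid_threshold_ordering_rejected(self):
        with pytest.raises(ValueError):
            StateThresholds(lo=0.9, qa_hi=0.8)


class TestStageAssignment:
    def _native_d_com(self, topo):
        return float(np.linalg.norm(
            topo.ref_positions_B[topo.protein_mask].mean(0)
            - topo.ref_positions_B[topo.dna_mask].mean(0)))

    def test_native_bound_frame_is_bs(self, toy_complex):
        t = toy_complex.topology
        fr = compute_frames(t.ref_positions_B, t)[0]
        assert assign_stage(fr, self._native_d_com(t)) == "BS"

    def test_far_separated_frame_is_us(self, toy_complex):
        t = toy_complex.topology
        x = t.ref_positions_B.copy()
        x[t.protein_mask] += 300.0
        fr = compute_frames(x, t)[0]
        assert assign_stage(fr, self._native_d_com(t)) == "US"

    def test_contact_without_native_interface_is_ec(self, toy_complex):
        t = toy_complex.topology
        # slide the protein along the duplex: close but non-native
        x = t.ref_positions_B.copy()
        dna_axis = x[t.dna_mask][-1] - x[t.dna_mask][0]
        x[t.protein_mask] += 2.5 * dna_axis / np.linalg.norm(dna_axis) * 10
        fr = compute_frames(x, t)[0]
        if fr.cutoff_contact_count > 0 and fr.q_idna < 0.1:
            assert assign_stage(fr, self._native_d_com(t)) == "EC"

    def test_recognition_only_binding_is_is(self, toy_complex):
        t = toy_complex.topology
        fr = compute_frames(t.ref_positions_B, t)[0]
        # construct a frame record with the recognition region natively bound
        # and the core unbound, below the full-interface threshold
        fr2 = ana.CoordinateFrame(
            q_idna=0.45, q_a=0.1, q_ib=0.4, d_com=fr.d_com,
            cutoff_contact_count=12,
            per_region_q={"recognition": 0.9, "core": 0.02},
        )
        assert assign_stage(fr2, self._native_d_com(t)) == "IS"

    def test_every_frame_gets_exactly_one_stage(self, toy_complex):
        t = toy_complex.topology
        rng = np.random.default_rng(3)
        d0 = self._native_d_com(t)
        labels = set()
        for _ in range(30):
            x = t.ref_positions_B.copy()
            x[t.protein_mask] += rng.uniform(-40, 40, 3)
            fr = compute_frames(x, t)[0]
            lab = assign_stage(fr, d0)
            assert lab in {"US", "EC", "IS", "BS"}
            labels.add(lab)
        assert {"US", "EC"} <= labels  # both ends of the pathway sampled


class TestWHAM:
    def test_single_temperature_equals_raw_histogram(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 5000)
        e = 0.5 * 2.0 * x**2
        f = wham_offsets([e], [1.0])
        assert f.tolist() == [0.0]
        w = wham_weights([e], [1.0], f, 1.0)
        surf = free_energy_profile(x, w, bins=25)
        hist, _ = np.histogram(x, bins=25)
        raw = -np.log(hist[hist > 0].astype(float))
        raw -= raw.min()
        assert np.allclose(surf.free_energy[surf.sampled], raw, atol=1e-12)

    def test_harmonic_profile_recovered_across_temperatures(self):
        k = 2.0
        temps = [0.7, 1.0, 1.4, 2.0]
        rng = np.random.default_rng(11)
        samples = [rng.normal(0, np.sqrt(T / k), 60000) for T in temps]
        energies = [0.5 * k * x**2 for x in samples]
        f = wham_offsets(energies, temps)
        # offsets are ratios of partition functions: f_k = 0.5 ln(T_0/T_k)
        expect = 0.5 * np.log(temps[0] / np.asarray(temps))
        assert np.allclose(f, expect, atol=0.01)
        w = wham_weights(energies, temps, f, target_temperature=1.0)
        surf = free_energy_profile(np.concatenate(samples), w, bins=41,
                                   ranges=[(-2.0, 2.0)])
        centers = 0.5 * (surf.edges[0][:-1] + surf.edges[0][1:])
        analytic = 0.5 * k * centers**2
        analytic -= analytic[surf.sampled].min()
        assert np.abs(surf.free_energy[surf.sampled]
                      - analytic[surf.sampled]).max() < 0.1

    def test_offsets_match_independent_histogram_wham(self):
        """Cross-check the self-consistency solver against a separately
        written histogram-based WHAM iteration on the same histograms."""
        k = 3.0
        temps = np.array([0.8, 1.0, 1.3])
        rng = np.random.default_rng(21)
        energies = [0.5 * k * rng.normal(0, np.sqrt(T / k), 30000) ** 2 for T in temps]
        edges = np.linspace(0.0, float(max(e.max() for e in energies)), 401)
        centers = 0.5 * (edges[:-1] + edges[1:])
        counts = np.array([np.histogram(e, bins=edges)[0] for e in energies])

        # oracle: classic histogram WHAM, iterated to convergence
        betas = 1.0 / temps
        n_k = counts.sum(axis=1).astype(float)
        f_or = np.zeros(len(temps))
        total = counts.sum(axis=0)
        for _ in range(20000):
            log_denom = logsumexp(
                np.log(n_k)[:, None] + f_or[:, None] - betas[:, None] * centers[None, :],
                axis=0)
            with np.errstate(divide="ignore"):
                log_p = np.where(total > 0, np.log(total) - log_denom, -np.inf)
            f_new = -logsumexp(log_p[None, :] - betas[:, None] * centers[None, :], axis=1)
            f_new -= f_new[0]
            if np.max(np.abs(f_new - f_or)) < 1e-12:
                break
            f_or = f_new

        # package solver fed the identical binned data
        pseudo = [np.repeat(centers, c) for c in counts]
        f_pkg = wham_offsets(pseudo, temps)
        assert np.allclose(f_pkg, f_or, atol=1e-3)

    def test_disjoint_energy_ranges_error_names_the_gap(self):
        with pytest.raises(ValueError, match="overlap.*T=1"):
            wham_offsets([np.array([0.0, 1.0]), np.array([50.0, 51.0])], [1.0, 1.1])

    def test_reweighted_populations_track_quadrature_and_temperature_trend(self):
        # deep narrow well (enthalpy-favored) vs shallow wide well
        def u(x):
            return np.minimum(0.5 * 60 * (x + 1.0) ** 2 - 2.0,
                              0.5 * 2.0 * (x - 1.0) ** 2)

        grid = np.linspace(-3, 4, 4001)
        temps = [0.6, 0.8, 1.0, 1.3]
        rng = np.random.default_rng(2)
        samples, energies = [], []
        for T in temps:
            p = np.exp(-(u(grid) - u(grid).min()) / T)
            p /= p.sum()
            x = rng.choice(grid, size=40000, p=p)
            samples.append(x)
            energies.append(u(x))
        f = wham_offsets(energies, temps)
        pooled = np.concatenate(samples)
        labels = np.where(pooled < 0, "deep", "wide")
        fractions = []
        for target in [0.65, 0.8, 1.0, 1.25]:
            w = wham_weights(energies, temps, f, target)
            pop = reweighted_populations(labels, w)
            # quadrature oracle at the same temperature
            pz = np.exp(-(u(grid) - u(grid).min()) / target)
            expect = pz[grid < 0].sum() / pz.sum()
            assert pop["deep"] == pytest.approx(expect, abs=0.02)
            fractions.append(pop["deep"])
        # enthalpy-favored state loses population as temperature rises
        assert all(a >= b - 1e-3 for a, b in zip(fractions, fractions[1:]))


class TestTables:
    def test_population_counting(self):
        states = ["A"] * 54 + ["I"] * 46 + ["A"] * 10
        stages = ["US"] * 100 + ["BS"] * 10
        table = population_table(states, stages)
        assert table.loc["US", "A"] == pytest.approx(0.54)
        assert table.loc["US", "I"] == pytest.approx(0.46)
        assert table.loc["US", "B"] == 0.0
        assert table.loc["US"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_missing_stage_is_omitted_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            table = population_table(["A", "I"], ["US", "US"])
        assert "BS" not in table.index
        assert "no assigned frames" in caplog.text

    def test_profile_zero_when_dissociated(self, toy_complex):
        t = toy_complex.topology
        x = t.ref_positions_B.copy()
        x[t.protein_mask] += 500.0
        prof = cutoff_contact_profile(x, t)
        assert prof["per_residue"].sum() == 0.0
        assert prof["per_nucleotide"].sum() == 0.0

    def test_profile_counts_single_persistent_pair(self, toy_complex):
        t = toy_complex.topology
        x = t.ref_positions_B.copy()
        x[t.protein_mask] += 500.0
        # park protein bead 0 next to the first nucleotide's sugar bead
        dna_idx = np.where(t.dna_mask)[0]
        sugar = next(b for b in dna_idx if t.beads[b].bead_kind.value == "SUGAR")
        x[0] = x[sugar] + np.array([3.0, 0, 0])
        prof = cutoff_contact_profile(np.array([x, x]), t, cutoff=8.0)
        res = t.beads[0].residue_index
        assert prof["per_residue"].loc[res] >= 1.0
        nt = (t.beads[sugar].chain_id, t.beads[sugar].residue_index)
        assert prof["per_nucleotide"].loc[nt] >= 1.0

    def test_constant_energies_have_zero_sd(self):
        b = EnergyBreakdown(0.0, -5.0, 0.2, -1.0, -2.0)
        table = energy_stage_stats([b] * 6, ["BS"] * 6)
        assert np.allclose(table[("BS", "sd")].to_numpy(), 0.0)
        assert table.loc[("E_LJ", "Native"), ("BS", "mean")] == -5.0

    def test_planted_gaussian_recovery(self):
        rng = np.random.default_rng(7)
        n = 4000
        vals = rng.normal(-12.0, 1.5, n)
        breakdowns = [EnergyBreakdown(0.0, v, 0.0, -1.0, -3.0) for v in vals]
        table = energy_stage_stats(breakdowns, ["IS"] * n)
        assert table.loc[("E_LJ", "Native"), ("IS", "mean")] == pytest.approx(
            -12.0, abs=3 * 1.5 / np.sqrt(n))
        assert table.loc[("E_LJ", "Native"), ("IS", "sd")] == pytest.approx(1.5, rel=0.1)


class TestMeanPassageTime:
    def _rec(self, steps, censored=False, max_steps=1000, dt=0.01):
        return FirstPassageRecord(
            seed=steps or 0, steps=None if censored else steps,
            time=None if censored else steps * dt, censored=censored,
            max_steps=max_steps, dt=dt)

    def test_identical_passage_times_have_zero_stderr(self):
        est = mean_passage_time([self._rec(100) for _ in range(10)])
        assert est.mean == pytest.approx(1.0)
        assert est.stderr == 0.0
        assert est.n_transitions == 10

    def test_all_censored_batch_returns_exactly_the_horizon(self):
        est = mean_passage_time(
            [self._rec(None, censored=True, max_steps=500) for _ in range(20)])
        assert est.mean == 500 * 0.01
        assert est.n_censored == 20

    def test_zero_runs_error(self):
        with pytest.raises(ValueError):
            mean_passage_time([])

    def test_censored_runs_contribute_the_observation_horizon(self):
        recs = [self._rec(200), self._rec(None, censored=True, max_steps=1000)]
        est = mean_passage_time(recs)
        assert est.mean == pytest.approx((200 * 0.01 + 1000 * 0.01) / 2)
        assert est.n_transitions == 1 and est.n_censored == 1
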
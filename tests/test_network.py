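"""Unit and property tests of the mass-action network core."""

import numpy as np
import pytest

from gababsim.network import (
    MOIETIES,
    SPECIES,
    IntegrationError,
    KineticParams,
    ReactionSpec,
    StimulusSchedule,
    build_signaling_network,
    conserved_totals,
    derive_k2x,
    mass_action_rhs,
    simulate_signaling,
)

STIM = StimulusSchedule(((0.0, 1.0, 1000.0),))


class TestKineticParams:
    def test_bounds_enforced(self):
        with pytest.raises(ValueError, match="k1"):
            KineticParams.unit(k1=1001.0)
        with pytest.raises(ValueError, match="rgs_post"):
            KineticParams.unit(rgs_post=0.01)
        with pytest.raises(ValueError, match="f_gaba"):
            KineticParams.unit(f_gaba=-1.0)

    def test_rgs_selected_by_kind(self):
        p = KineticParams.unit(rgs_post=2.0, rgs_pre_E=3.0, rgs_pre_I=4.0)
        assert p.rgs_for("post") == 2.0
        assert p.rgs_for("pre_E") == 3.0
        assert p.rgs_for("pre_I") == 4.0


class TestAffinity:
    def test_printed_value(self):
        assert derive_k2x(1.0) == pytest.approx(6.1105e-4, rel=1e-12)

    @pytest.mark.parametrize("k2", [1e-4, 1.0, 37.2, 1000.0])
    def test_dissociation_constant_invariant(self, k2):
        """kb/kf of agonist binding is 110 nM for every k2."""
        assert derive_k2x(k2) / (5.555e-6 * k2) == pytest.approx(110.0)

    def test_nonpositive_k2_rejected(self):
        with pytest.raises(ValueError):
            derive_k2x(0.0)


class TestBuildNetwork:
    def test_post_initial_concentrations(self, post_network):
        y0, idx = post_network.y0, post_network.index
        assert y0[idx["GIRK"]] == 1000.0
        assert y0[idx["VGCC"]] == 0.0
        assert y0[idx["GABA_B_R"]] == 400.0
        assert y0[idx["G_i"]] == 2600.0

    def test_presynaptic_initial_concentrations(self):
        p = KineticParams.unit(rgs_pre_E=2.5)
        net = build_signaling_network("pre_E", p)
        assert net.y0[net.index["GIRK"]] == 0.0
        assert net.y0[net.index["VGCC"]] == 100.0
        assert net.y0[net.index["RGS"]] == 2500.0

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            build_signaling_network("soma", KineticParams.unit())

    def test_k3_zero_blocks_g_protein_activation(self):
        """With the activation multiplier zeroed no GiaGTP ever forms."""
        net = build_signaling_network("post", KineticParams.unit(k3=0.0))
        traj = simulate_signaling(net, STIM, t_end=500.0, dt_out=5.0)
        assert traj["GiaGTP"].max() == 0.0
        assert traj["Gibg"].max() == 0.0

    def test_release_reactions_appended(self):
        net = build_signaling_network("pre_E", KineticParams.unit(),
                                      include_release=True)
        names = [r.name for r in net.reactions]
        assert names[-4:] == ["R16", "R17", "R18", "R19"]
        assert net.y0[net.index["Ffactor"]] == 1000.0

    def test_unknown_species_rejected(self):
        with pytest.raises(ValueError, match="unknown species"):
            ReactionSpec("bad", (("nothing", 1),), (), kf=1.0)


def brute_force_rhs(c, network, gaba_flux=0.0):
    """Independent oracle: loop over reactions, accumulate term by term,
    multiplying concentrations in species-index order as the vectorized
    implementation does."""
    dc = np.zeros(network.n_species)
    for j, r in enumerate(network.reactions):
        vf = 1.0
        for i in np.nonzero(network.Ef[j])[0]:
            vf *= c[i] ** network.Ef[j, i]
        vf = r.kf * vf
        vb = 0.0
        if r.kb > 0:
            vb = 1.0
            for i in np.nonzero(network.Eb[j])[0]:
                vb *= c[i] ** network.Eb[j, i]
            vb = r.kb * vb
        for sp, nu in r.reactants:
            dc[network.index[sp]] -= nu * (vf - vb)
        for sp, nu in r.products:
            dc[network.index[sp]] += nu * (vf - vb)
    dc[network.index["gaba"]] += gaba_flux
    return dc


class TestMassActionRHS:
    def test_zero_state_zero_derivative(self, post_network):
        dc = mass_action_rhs(np.zeros(post_network.n_species), post_network)
        assert np.all(dc == 0.0)

    def test_isolated_rgs_binding_rate(self, post_network):
        """R8 alone: d[GiaGTPRGS]/dt = 2e-6 * 100 * 1000 = 0.2 nM/ms."""
        dc = mass_action_rhs({"GiaGTP": 100.0, "RGS": 1000.0},
                             post_network)
        assert dc[post_network.index["GiaGTPRGS"]] == pytest.approx(0.2)

    def test_flux_enters_gaba_only(self, post_network):
        c = np.zeros(post_network.n_species)
        dc = mass_action_rhs(c, post_network, gaba_flux=123.0)
        assert dc[post_network.index["gaba"]] == 123.0
        assert np.count_nonzero(dc) == 1

    def test_matches_bruteforce_oracle(self):
        """Per-reaction rate laws are identical formulae; the vectorized
        sum and the loop accumulate in different orders, so agreement is
        to float round-off (a few ulp)."""
        net = build_signaling_network("pre_E", KineticParams.unit(),
                                      include_release=True)
        rng = np.random.default_rng(42)
        for _ in range(100):
            c = rng.uniform(0.0, 2000.0, net.n_species)
            expected = brute_force_rhs(c, net)
            np.testing.assert_allclose(mass_action_rhs(c, net), expected,
                                       rtol=1e-14, atol=1e-18)

    def test_invalid_states_rejected(self, post_network):
        bad = np.zeros(post_network.n_species)
        bad[0] = np.nan
        with pytest.raises(ValueError):
            mass_action_rhs(bad, post_network)
        bad[0] = -1.0
        with pytest.raises(ValueError):
            mass_action_rhs(bad, post_network)


class TestSimulate:
    def test_zero_stimulus_stays_resting(self, post_network):
        traj = simulate_signaling(post_network, None, t_end=500.0,
                                  dt_out=10.0)
        for sp in ("gabaGABA_B_R", "GiaGTP", "Gibg", "GIRKGibg"):
            assert traj[sp].max() == 0.0

    def test_trajectory_grid(self, post_network):
        traj = simulate_signaling(post_network, STIM, t_end=100.0,
                                  dt_out=2.5)
        assert traj.times[0] == 0.0
        assert np.all(np.diff(traj.times) > 0)
        assert traj.states.shape == (len(traj.times),
                                     post_network.n_species)

    def test_nonnegative_output(self, post_network):
        traj = simulate_signaling(post_network, STIM, t_end=1000.0)
        assert traj.states.min() >= 0.0

    @pytest.mark.parametrize("kind", ["post", "pre_E"])
    def test_moiety_conservation(self, kind):
        """Every conserved moiety stays within 1e-6 relative error."""
        net = build_signaling_network(kind, KineticParams.unit(),
                                      include_release=(kind == "pre_E"))
        traj = simulate_signaling(net, STIM, t_end=2000.0, dt_out=20.0)
        tot0 = conserved_totals(net.y0, net.species)
        for state in traj.states[::10]:
            tot = conserved_totals(state, net.species)
            for name, v0 in tot0.items():
                if v0 > 0:
                    assert abs(tot[name] - v0) / v0 < 1e-6, name

    def test_gaba_moiety_grows_by_integrated_flux(self, post_network):
        traj = simulate_signaling(post_network, STIM, t_end=300.0)
        gaba_like = (traj["gaba"] + traj["gabaOut"] + traj["gabaGABA_B_R"]
                     + traj["gabaGABA_B_RGi"] + traj["gabaGABA_B_RGibg"])
        # 1000 nM/ms for 1 ms -> 1000 nM in the gaba moiety
        assert gaba_like[-1] == pytest.approx(1000.0, rel=1e-6)

    def test_matches_explicit_euler_oracle(self):
        """Stiff solution agrees with a fine-step explicit first-order
        integrator within 0.5% relative on a short horizon."""
        net = build_signaling_network("post", KineticParams.unit())
        traj = simulate_signaling(net, STIM, t_end=50.0, dt_out=10.0)
        dt = 1e-3
        c = net.y0.copy()
        t = 0.0
        checkpoints = {}
        n_steps = int(round(50.0 / dt))
        stim = STIM
        for k in range(n_steps):
            flux = stim.flux_at(t)
            dc = net.rhs(c)
            dc[net.index["gaba"]] += flux
            c = c + dt * dc
            t = (k + 1) * dt
            if abs(t / 10.0 - round(t / 10.0)) < 1e-9:
                checkpoints[round(t)] = c.copy()
        for t_out, c_euler in checkpoints.items():
            i = int(np.argmin(np.abs(traj.times - t_out)))
            scale = np.maximum(np.abs(c_euler), 1e-3 * c_euler.max())
            rel = np.abs(traj.states[i] - c_euler) / scale
            assert rel.max() < 5e-3

    def test_monotone_dose_response(self):
        """Steady-state bound effector is nondecreasing in the agonist
        clamp concentration."""
        bound = []
        for clamp in (1.0, 10.0, 100.0, 1000.0, 10000.0):
            net = build_signaling_network("post", KineticParams.unit())
            stim = StimulusSchedule(clamps={"gaba": clamp})
            traj = simulate_signaling(net, stim, t_end=200000.0,
                                      dt_out=10000.0)
            s = traj.final_state()
            idx = net.index
            bound.append(sum(s[idx[f"GIRKGibg{n if n > 1 else ''}"]]
                             for n in range(1, 5)))
        assert np.all(np.diff(bound) >= -1e-9)

    def test_overlapping_pulses_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            StimulusSchedule(((0.0, 5.0, 10.0), (3.0, 5.0, 10.0)))

    def test_t_end_validation(self, post_network):
        with pytest.raises(ValueError):
            simulate_signaling(post_network, None, t_end=0.0)


class TestConservedTotals:
    def test_initial_gibg_total(self, post_network):
        tot = conserved_totals(post_network.y0, post_network.species)
        assert tot["Gibg"] == 2600.0
        assert tot["receptor"] == 400.0

    def test_quadruple_occupancy_multiplicity(self):
        tot = conserved_totals({"GIRKGibg4": 10.0})
        assert tot["Gibg"] == 40.0
        assert tot["GIRK"] == 10.0

    def test_moiety_definitions_cover_species(self):
        # every cascade species except the free agonist pools belongs to
        # at least one moiety
        covered = set()
        for members in MOIETIES.values():
            covered |= set(members)
        assert set(SPECIES) - covered == {"gaba", "gabaOut"}
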
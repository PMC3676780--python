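"""MWC receptor-cluster equilibria against brute-force Boltzmann oracles."""

import numpy as np
import pytest
from scipy.optimize import brentq

from chemoscale.mwc_cluster import (
    ClusterSpec,
    DoseResponse,
    TrimerParams,
    default_tar,
    default_tsr,
    delta_f,
    dose_response,
    free_energy_levels,
    p_on_cluster,
    p_on_mixed,
    p_on_single_site,
    p_on_trimer,
    transition_grid,
)


def boltzmann_p_on(trimer: TrimerParams, L: float) -> float:
    """Brute-force partition sum over the eight explicit free-energy levels."""
    def weights(e0, kds):
        k1, k2, k3 = kds
        poly = [1.0, 3.0 * L / k1, 3.0 * L**2 / (k1 * k2), L**3 / (k1 * k2 * k3)]
        return [np.exp(-e0) * c for c in poly]

    w_on = weights(trimer.e_on, trimer.kd_on)
    w_off = weights(trimer.e_off, trimer.kd_off)
    return sum(w_on) / (sum(w_on) + sum(w_off))


def random_trimer(rng) -> TrimerParams:
    return TrimerParams(
        e_on=rng.uniform(-6.0, 3.0),
        e_off=rng.uniform(-2.0, 2.0),
        kd_on=tuple(np.exp(rng.uniform(np.log(0.01), np.log(10.0), 3))),
        kd_off=tuple(np.exp(rng.uniform(np.log(0.01), np.log(10.0), 3))),
    )


class TestFreeEnergyLevels:
    def test_one_bound_level(self):
        tr = TrimerParams(e_on=0.0, e_off=0.0, kd_on=(1.0, 1.0, 1.0), kd_off=(1.0, 1.0, 1.0))
        lev = free_energy_levels(tr, 1.0)
        assert lev.energy["on"][1] == pytest.approx(-np.log(3.0))
        assert lev.energy["on"][3] == pytest.approx(0.0)  # L^3/(1*1*1) -> -log 1

    def test_ligand_free_flags(self):
        lev = free_energy_levels(default_tar(), 0.0)
        assert lev.occupied["on"][0] and lev.occupied["off"][0]
        assert not lev.occupied["on"][1:].any()
        assert lev.energy["on"][0] == default_tar().e_on
        assert np.isnan(lev.energy["on"][1])

    def test_negative_ligand_rejected(self):
        with pytest.raises(ValueError):
            free_energy_levels(default_tar(), -1.0)

    def test_degeneracy_factors(self, rng):
        """Boltzmann weights of the levels carry the 3,3,1 degeneracies of a
        three-site binding polynomial (oracle: enumerate 2^3 site microstates
        with per-site binding factors)."""
        L = 0.7
        k = 0.3
        tr = TrimerParams(e_on=0.0, e_off=0.0, kd_on=(k, k, k), kd_off=(1.0, 1.0, 1.0))
        lev = free_energy_levels(tr, L)
        w = np.exp(-lev.energy["on"])
        # microstate oracle: each of 3 identical sites contributes L/k when occupied
        micro = np.zeros(4)
        for occ in range(8):
            j = bin(occ).count("1")
            micro[j] += (L / k) ** j
        assert np.allclose(w, micro, rtol=1e-12)


class TestDeltaF:
    def test_ligand_free(self):
        tr = default_tar()
        assert delta_f(tr, 0.0) == pytest.approx(tr.e_on - tr.e_off)

    def test_identical_kds_constant(self):
        tr = TrimerParams(e_on=-2.0, kd_on=(0.3, 0.4, 0.5), kd_off=(0.3, 0.4, 0.5))
        for L in [0.0, 0.1, 10.0, 1e6]:
            assert delta_f(tr, L) == pytest.approx(-2.0, abs=1e-12)

    def test_zero_crossing_matches_rootfind_oracle(self, sharp_trimer):
        """delta_f crosses 0 where (1+L/0.02)^3/(1+L/0.5)^3 = e^6."""
        oracle = brentq(
            lambda L: (1 + L / 0.02) ** 3 / (1 + L / 0.5) ** 3 - np.exp(6.0),
            1e-6,
            1e3,
        )
        ours = brentq(lambda L: delta_f(sharp_trimer, L), 1e-6, 1e3)
        assert ours == pytest.approx(oracle, rel=1e-10)

    def test_no_overflow_at_extreme_ligand(self):
        assert np.isfinite(delta_f(default_tar(), 1e300))


class TestActivity:
    def test_trivial_values(self):
        tr = TrimerParams(e_on=-2.0, e_off=0.0, kd_on=(1, 1, 1), kd_off=(1, 1, 1))
        assert p_on_trimer(tr, 0.0) == pytest.approx(1.0 / (1.0 + np.exp(-2.0)))
        tr0 = TrimerParams(e_on=0.0, e_off=0.0, kd_on=(1, 1, 1), kd_off=(1, 1, 1))
        assert p_on_trimer(tr0, 0.5) == pytest.approx(0.5)

    def test_partition_sum_oracle(self, rng):
        """Logistic form equals the brute-force eight-level Boltzmann sum."""
        for _ in range(30):
            tr = random_trimer(rng)
            L = float(np.exp(rng.uniform(np.log(1e-3), np.log(1e2))))
            assert p_on_trimer(tr, L) == pytest.approx(
                boltzmann_p_on(tr, L), abs=1e-12
            )

    def test_cluster_reduces_to_trimer(self, sharp_trimer):
        for L in [0.0, 0.05, 0.2, 1.0]:
            assert p_on_cluster(1, sharp_trimer, L) == p_on_trimer(sharp_trimer, L)

    def test_cluster_substitution(self):
        # delta_f = 0.5 per trimer, n = 6 -> 1/(1+e^3)
        tr = TrimerParams(e_on=0.5, e_off=0.0, kd_on=(1, 1, 1), kd_off=(1, 1, 1))
        assert p_on_cluster(6, tr, 0.0) == pytest.approx(1.0 / (1.0 + np.exp(3.0)))

    def test_cluster_limit_is_step(self, sharp_trimer):
        assert p_on_cluster(500, sharp_trimer, 0.0) == pytest.approx(1.0)  # df < 0
        assert p_on_cluster(500, sharp_trimer, 100.0) == pytest.approx(0.0, abs=1e-12)

    def test_cluster_monotone_in_n(self, sharp_trimer):
        L = 0.15  # just below the transition: df < 0, activity grows with n
        vals = [p_on_cluster(n, sharp_trimer, L) for n in (1, 2, 4, 8, 16)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_invalid_n(self, sharp_trimer):
        with pytest.raises(ValueError):
            p_on_cluster(0, sharp_trimer, 1.0)


class TestMixedCluster:
    def test_reduces_to_pure_cluster(self):
        spec = ClusterSpec(n_a=4, n_s=0)
        for L in [0.0, 0.1, 1.0]:
            assert p_on_mixed(spec, L, "Tar") == pytest.approx(
                p_on_cluster(4, spec.tar, L), abs=1e-14
            )

    def test_symmetric_swap(self):
        tar = default_tar()
        tsr_same = TrimerParams(
            receptor_type="Tsr", e_on=tar.e_on, e_off=tar.e_off,
            kd_on=tar.kd_on, kd_off=tar.kd_off,
        )
        a = p_on_mixed(ClusterSpec(2, 5, tar=tar, tsr=tsr_same), 0.3, "Tar")
        b = p_on_mixed(ClusterSpec(5, 2, tar=tar, tsr=tsr_same), 0.3, "Tsr")
        assert a == pytest.approx(b, abs=1e-14)

    def test_tar_count_increases_amplitude(self):
        """More Tar trimers -> larger response amplitude to the Tar ligand,
        with Tsr contributing a constant offset."""
        tar, tsr = default_tar(), default_tsr()
        grid = transition_grid(tar, n_points=50)
        amps = []
        for n_a in (1, 3, 6, 12):
            spec = ClusterSpec(n_a=n_a, n_s=6, tar=tar, tsr=tsr)
            p = np.asarray(p_on_mixed(spec, grid, "Tar"))
            amps.append(p.max() - p.min())
        assert all(b > a for a, b in zip(amps, amps[1:]))

    def test_unknown_target(self):
        with pytest.raises(ValueError):
            p_on_mixed(ClusterSpec(1, 1), 1.0, "Trg")

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            ClusterSpec(0, 0)


class TestDoseResponse:
    def test_attractant_curve_decreasing(self, sharp_trimer):
        curve = dose_response(sharp_trimer, transition_grid(sharp_trimer), n=6)
        assert np.all(np.diff(curve.p_on) <= 0)

    def test_repellent_like_curve_increasing(self):
        tr = TrimerParams(e_on=2.0, kd_on=(0.02, 0.02, 0.02), kd_off=(0.5, 0.5, 0.5))
        curve = dose_response(tr, transition_grid(tr))
        assert np.all(np.diff(curve.p_on) >= 0)

    def test_flat_below_kd(self, sharp_trimer):
        grid = np.geomspace(1e-9, sharp_trimer.kd_off[0] / 100.0, 25)
        curve = dose_response(sharp_trimer, grid)
        p0 = p_on_trimer(sharp_trimer, 0.0)
        assert np.allclose(curve.p_on, p0, atol=1e-3)

    def test_endpoints_match_pointwise(self, sharp_trimer):
        grid = transition_grid(sharp_trimer)
        curve = dose_response(sharp_trimer, grid, n=3)
        assert curve.p_on[0] == p_on_cluster(3, sharp_trimer, grid[0])
        assert curve.p_on[-1] == p_on_cluster(3, sharp_trimer, grid[-1])

    def test_grid_validation(self, sharp_trimer):
        with pytest.raises(ValueError):
            dose_response(sharp_trimer, np.array([]))
        with pytest.raises(ValueError):
            dose_response(sharp_trimer, np.geomspace(0.01, 1.0, 5))

    def test_csv_round_trip(self, sharp_trimer, tmp_path):
        curve = dose_response(sharp_trimer, transition_grid(sharp_trimer))
        path = tmp_path / "curve.csv"
        curve.to_csv(path)
        back = DoseResponse.from_csv(path)
        assert np.allclose(back.L, curve.L)
        assert np.allclose(back.p_on, curve.p_on)


class TestSingleSite:
    def test_matches_explicit_formula(self):
        L = np.array([0.0, 0.05, 0.5, 5.0])
        expected = 1.0 / (1.0 + np.exp(-2.0 + np.log((1 + L / 0.02) / (1 + L / 0.5))))
        assert np.allclose(p_on_single_site(-2.0, 0.5, 0.02, L), expected, atol=1e-14)
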
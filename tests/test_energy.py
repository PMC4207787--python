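import numpy as np
import pytest

from dimerstab.energy import (
    BindingEnergyResult, EnergyTrajectory, ddg_relaxed, ddg_rigid,
    read_energy_tables, select_candidates, toy_energy,
)
from dimerstab.synth import SynthSpec, make_energy_traj


def traj(role, source, energies):
    return EnergyTrajectory(role=role, source=source,
                            energies=np.asarray(energies, dtype=float))


class TestToyPotential:
    def test_lj_minimum_closed_form(self):
        """Two neutral atoms at r = 2^(1/6) sigma sit at the LJ minimum -eps."""
        sigma, eps = 3.4, 0.25
        r = 2 ** (1 / 6) * sigma
        coords = np.array([[0.0, 0, 0], [r, 0, 0]])
        e = toy_energy(coords, epsilon=[eps, eps], sigma=[sigma, sigma],
                       charge=[0.0, 0.0])
        assert e == pytest.approx(-eps, abs=1e-12)

    def test_vanishes_at_large_separation(self):
        coords = np.array([[0.0, 0, 0], [1e6, 0, 0]])
        e = toy_energy(coords, epsilon=[0.2, 0.2], sigma=[3.0, 3.0],
                       charge=[1.0, -1.0])
        assert abs(e) < 1e-8

    def test_three_atoms_match_hand_summed_pairs(self):
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0], [0, 4.0, 0]])
        eps = np.array([0.1, 0.2, 0.3])
        sig = np.array([3.0, 3.2, 3.4])
        q = np.array([0.5, -0.5, 0.25])

        def pair(i, j):
            r = np.linalg.norm(coords[i] - coords[j])
            e_ij = np.sqrt(eps[i] * eps[j])
            s_ij = (sig[i] + sig[j]) / 2
            lj = 4 * e_ij * ((s_ij / r) ** 12 - (s_ij / r) ** 6)
            coul = 332.06 * q[i] * q[j] / (4 * r * r)
            return lj + coul

        expected = pair(0, 1) + pair(0, 2) + pair(1, 2)
        assert toy_energy(coords, eps, sig, q) == pytest.approx(
            expected, abs=1e-10)

    def test_coincident_atoms_error(self):
        coords = np.zeros((2, 3))
        with pytest.raises(ValueError, match="zero"):
            toy_energy(coords, [0.1, 0.1], [3.0, 3.0], [0.0, 0.0])


class TestDdgRigid:
    def test_non_interacting_gives_zero(self, rng):
        r = rng.normal(-5000, 3, 30)
        l = rng.normal(-40, 1, 30)
        val = ddg_rigid(traj("complex", "extracted", r + l),
                        traj("receptor", "extracted", r),
                        traj("ligand", "extracted", l))
        assert val == pytest.approx(0.0, abs=1e-9)

    def test_constant_interaction(self):
        n = 25
        r = np.full(n, -100.0)
        l = np.full(n, -10.0)
        c = r + l - 25.0
        assert ddg_rigid(traj("complex", "extracted", c),
                         traj("receptor", "extracted", r),
                         traj("ligand", "extracted", l)) == -25.0

    def test_matches_spreadsheet_mean_of_last_twenty(self, rng):
        n = 25
        c = rng.normal(-5100, 4, n)
        r = rng.normal(-5000, 4, n)
        l = rng.normal(-50, 2, n)
        expected = np.mean((c - r - l)[-20:])
        assert ddg_rigid(traj("complex", "extracted", c),
                         traj("receptor", "extracted", r),
                         traj("ligand", "extracted", l)) == pytest.approx(
            expected, abs=1e-12)

    def test_requires_extracted_sources(self):
        e = np.zeros(25)
        with pytest.raises(ValueError, match="extracted"):
            ddg_rigid(traj("complex", "extracted", e),
                      traj("receptor", "independent", e),
                      traj("ligand", "extracted", e))

    def test_too_few_snapshots(self):
        e = np.zeros(10)
        with pytest.raises(ValueError, match="snapshots"):
            ddg_rigid(traj("complex", "extracted", e),
                      traj("receptor", "extracted", e),
                      traj("ligand", "extracted", e))

    def test_misaligned_lengths(self):
        with pytest.raises(ValueError, match="aligned"):
            ddg_rigid(traj("complex", "extracted", np.zeros(25)),
                      traj("receptor", "extracted", np.zeros(24)),
                      traj("ligand", "extracted", np.zeros(25)))


class TestDdgRelaxed:
    def test_degenerate_equals_rigid(self, rng):
        c = rng.normal(-5100, 4, 30)
        r = rng.normal(-5000, 4, 30)
        l = rng.normal(-50, 2, 30)
        rigid = ddg_rigid(traj("complex", "extracted", c),
                          traj("receptor", "extracted", r),
                          traj("ligand", "extracted", l))
        relaxed = ddg_relaxed(traj("complex", "extracted", c),
                              traj("receptor", "independent", r),
                              traj("ligand", "independent", l))
        assert relaxed == pytest.approx(rigid, abs=1e-12)

    def test_relaxation_shifts_additively(self, rng):
        c = rng.normal(-5100, 4, 30)
        r = rng.normal(-5000, 4, 30)
        l = rng.normal(-50, 2, 30)
        rigid = ddg_rigid(traj("complex", "extracted", c),
                          traj("receptor", "extracted", r),
                          traj("ligand", "extracted", l))
        relaxed = ddg_relaxed(traj("complex", "extracted", c),
                              traj("receptor", "independent", r - 5.0),
                              traj("ligand", "independent", l))
        assert relaxed == pytest.approx(rigid + 5.0, abs=1e-10)

    def test_noisy_planted_value_within_monte_carlo_band(self):
        """Planted -25 with sigma=2 snapshot noise: each 20-snapshot estimate
        lies within 3 standard errors of truth."""
        sem = 2.0 / np.sqrt(20)
        for seed in range(20):
            spec = SynthSpec(seed=seed, ddg_noise=2.0)
            trajs = make_energy_traj(spec, 0, -25.0)
            est = ddg_rigid(trajs[("complex", "extracted")],
                            trajs[("receptor", "extracted")],
                            trajs[("ligand", "extracted")])
            assert abs(est - (-25.0)) <= 3 * sem


class TestSelectCandidates:
    def _res(self, cid, rigid, relaxed):
        return BindingEnergyResult(cid, rigid, relaxed)

    def test_or_semantics(self):
        selected = select_candidates(
            [self._res("a", -25.0, -10.0)], threshold=-20.0)
        assert [r.compound_id for r in selected] == ["a"]

    def test_both_weak_excluded(self):
        assert select_candidates(
            [self._res("a", -10.0, -10.0)], threshold=-20.0) == []

    def test_sorted_best_first_with_id_ties(self):
        results = [self._res("b", -22.0, -5.0), self._res("a", -22.0, -5.0),
                   self._res("c", -30.0, -5.0)]
        got = [r.compound_id for r in select_candidates(results)]
        assert got == ["c", "a", "b"]

    def test_matches_brute_force_scan(self, rng):
        results = [self._res(f"c{i:03d}", float(rng.uniform(-40, 0)),
                             float(rng.uniform(-40, 0))) for i in range(200)]
        got = {r.compound_id for r in select_candidates(results,
                                                        threshold=-20.0)}
        expected = {r.compound_id for r in results
                    if r.ddg_rigid <= -20.0 or r.ddg_relaxed <= -20.0}
        assert got == expected

    def test_selection_monotone_in_ddg(self, rng):
        """Making a selected compound's energy more favorable never drops it."""
        results = [self._res(f"c{i}", float(rng.uniform(-30, -10)), -5.0)
                   for i in range(50)]
        before = {r.compound_id for r in select_candidates(results)}
        improved = [BindingEnergyResult(r.compound_id, r.ddg_rigid - 1.0,
                                        r.ddg_relaxed) for r in results]
        after = {r.compound_id for r in select_candidates(improved)}
        assert before <= after

    def test_truncation(self):
        results = [self._res(f"c{i}", -30.0 + i * 0.1, 0.0)
                   for i in range(30)]
        got = select_candidates(results, threshold=-20.0, max_candidates=5)
        assert len(got) == 5
        assert got[0].compound_id == "c0"


class TestEnergyIO:
    def test_round_trip_csv(self, tmp_path):
        import pandas as pd
        spec = SynthSpec(seed=1, n_energy_snapshots=25)
        trajs = make_energy_traj(spec, 3, -25.0)
        rows = []
        for (role, source), t in trajs.items():
            for k, e in enumerate(t.energies):
                rows.append({"compound_id": "CPD000003", "role": role,
                             "source": source, "snapshot_ps": float(k),
                             "energy_kcal_mol": e})
        p = tmp_path / "energies.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        back = read_energy_tables(p)
        t = back["CPD000003"][("complex", "extracted")]
        np.testing.assert_allclose(
            t.energies, trajs[("complex", "extracted")].energies)
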
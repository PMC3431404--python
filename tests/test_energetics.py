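"""OBC Born radii vs quadrature, GB limits, term additivity,
Cheng-Prusoff conversions."""

import numpy as np
import pytest
from scipy import integrate

from ionloop.constants import F_ELEC, R_GAS
from ionloop.energetics import (GbParameters, InhibitionAssay, _hct_integral,
                                binding_dg, born_radii, cheng_prusoff_ddg,
                                cheng_prusoff_ki, coulomb_energy, gb_energy,
                                gbsa_binding_energy, lj_energy,
                                mg_bound_waters, sa_energy)
from ionloop.errors import AnalysisError, ParameterError
from ionloop.structio import SelectionGroup, Topology

PARAMS = GbParameters()


def make_top(n, charges, radii, sigmas=None, epsilons=None, screens=None):
    top = Topology(
        names=np.array([f"X{i}" for i in range(n)], dtype=object),
        elements=np.array(["C"] * n, dtype=object),
        masses=np.full(n, 12.011),
        resids=np.arange(1, n + 1),
        resnames=np.array(["LIG"] * n, dtype=object),
        chainids=np.array(["A"] * n, dtype=object))
    top.charges = np.asarray(charges, dtype=float)
    top.radii = np.asarray(radii, dtype=float)
    top.sigmas = (np.zeros(n) if sigmas is None
                  else np.asarray(sigmas, dtype=float))
    top.epsilons = (np.zeros(n) if epsilons is None
                    else np.asarray(epsilons, dtype=float))
    top.screens = (np.full(n, 0.8) if screens is None
                   else np.asarray(screens, dtype=float))
    return top


def quad_descreen(d, rho_i, sr_j):
    """Independent quadrature of the descreening integral: the angular
    part done analytically, the radial part numerically."""
    lo, hi = max(rho_i, d - sr_j), d + sr_j
    if hi <= lo:
        return 0.0

    def f(r):
        mu_star = (r * r + d * d - sr_j * sr_j) / (2 * r * d)
        return np.clip((1.0 - mu_star) / 2.0, 0.0, 1.0) / (r * r)

    return integrate.quad(f, lo, hi, limit=200, epsabs=1e-13,
                          epsrel=1e-13)[0]


class TestBornRadii:
    def test_isolated_atom_reduced_radius(self):
        top = make_top(1, [1.0], [0.2])
        r_eff = born_radii(top, np.zeros((1, 3)), PARAMS)
        assert r_eff[0] == pytest.approx(0.2 - PARAMS.offset, abs=1e-12)

    @pytest.mark.parametrize("d", [0.25, 0.3, 0.5, 1.0])
    def test_two_atom_matches_quadrature(self, d):
        rho = np.array([0.2, 0.17])
        screens = np.array([0.8, 0.85])
        top = make_top(2, [0.0, 0.0], rho, screens=screens)
        frame = np.array([[0.0, 0, 0], [d, 0, 0]])
        got = born_radii(top, frame, PARAMS)
        rho_red = rho - PARAMS.offset
        for i, j in ((0, 1), (1, 0)):
            psi = quad_descreen(d, rho_red[i],
                                screens[j] * rho_red[j]) * rho_red[i]
            inner = PARAMS.alpha * psi - PARAMS.beta * psi ** 2 \
                + PARAMS.gamma * psi ** 3
            expect = 1.0 / (1.0 / rho_red[i] - np.tanh(inner) / rho[i])
            assert got[i] == pytest.approx(expect, abs=1e-4)

    def test_hct_integral_engulfed_branch(self):
        # atom i entirely inside the neighbour's scaled sphere
        got = _hct_integral(np.array([0.05]), np.array(0.15),
                            np.array(0.3))[0]
        assert got == pytest.approx(quad_descreen(0.05, 0.15, 0.3),
                                    abs=1e-10)

    def test_monotone_growth_as_neighbor_approaches(self):
        rho = np.array([0.2, 0.17])
        top = make_top(2, [0.0, 0.0], rho)
        radii = []
        for d in [2.0, 1.0, 0.6, 0.45, 0.38]:
            frame = np.array([[0.0, 0, 0], [d, 0, 0]])
            radii.append(born_radii(top, frame, PARAMS)[0])
        assert all(a <= b + 1e-15 for a, b in zip(radii, radii[1:]))
        assert all(r >= rho[0] - PARAMS.offset for r in radii)

    def test_radius_below_offset_rejected(self):
        top = make_top(1, [0.0], [0.005])
        with pytest.raises(ParameterError):
            born_radii(top, np.zeros((1, 3)), PARAMS)


class TestGbEnergy:
    def test_single_ion_analytic_born(self):
        # -(f_el/2)(1 - 1/78.5) q^2 / R with R = 0.2 nm
        e = gb_energy([1.0], np.zeros((1, 3)), [0.2], PARAMS)
        expect = -(F_ELEC / 2) * (1 - 1 / 78.5) / 0.2
        assert e == pytest.approx(expect, rel=1e-12)
        assert e == pytest.approx(-342.9, abs=0.05)

    def test_zero_charges_zero_energy(self):
        frame = np.random.default_rng(0).normal(size=(5, 3))
        assert gb_energy(np.zeros(5), frame, np.full(5, 0.15),
                         PARAMS) == 0.0

    def test_screened_coulomb_limit(self):
        R = np.array([0.15, 0.2])
        r = 50 * R.max()
        frame = np.array([[0.0, 0, 0], [r, 0, 0]])
        q = np.array([1.0, 1.0])
        total = gb_energy(q, frame, R, PARAMS)
        self_terms = sum(gb_energy([qi], np.zeros((1, 3)), [Ri], PARAMS)
                         for qi, Ri in zip(q, R))
        pair = total - self_terms
        expect = -F_ELEC * (1 - 1 / 78.5) / r
        assert pair == pytest.approx(expect, rel=1e-3)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(8)
        frame = rng.normal(size=(6, 3))
        q = rng.normal(size=6)
        R = rng.uniform(0.1, 0.25, size=6)
        e0 = gb_energy(q, frame, R, PARAMS)
        quat, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(quat) < 0:
            quat[:, 0] = -quat[:, 0]
        moved = frame @ quat.T + rng.normal(size=3)
        assert gb_energy(q, moved, R, PARAMS) == pytest.approx(
            e0, abs=1e-9)


class TestPairwiseTerms:
    def test_coulomb_and_lj_match_direct_summation(self):
        """Vectorised terms equal an independent plain-loop summation
        on a random 8-atom fixture, to 1e-6 kJ/mol."""
        rng = np.random.default_rng(5)
        n = 8
        frame = rng.uniform(0, 1.2, size=(n, 3))
        q = rng.normal(0, 0.5, size=n)
        sig = rng.uniform(0.25, 0.35, size=n)
        eps = rng.uniform(0.1, 0.9, size=n)
        e_c, e_lj = 0.0, 0.0
        for i in range(n):
            for j in range(i + 1, n):
                r = float(np.linalg.norm(frame[i] - frame[j]))
                e_c += F_ELEC * q[i] * q[j] / r
                s = 0.5 * (sig[i] + sig[j])
                e = np.sqrt(eps[i] * eps[j])
                e_lj += 4 * e * ((s / r) ** 12 - (s / r) ** 6)
        assert coulomb_energy(q, frame) == pytest.approx(e_c, abs=1e-6)
        assert lj_energy(sig, eps, frame) == pytest.approx(e_lj, abs=1e-6)


class TestGbsaBinding:
    def ion_pair(self, separation):
        top = make_top(2, [1.0, -1.0], [0.2, 0.15],
                       sigmas=[0.25, 0.3], epsilons=[0.4, 0.6])
        frame = np.array([[0.0, 0, 0], [separation, 0, 0]])
        return top, frame

    def test_distant_ion_binds_nothing(self):
        top, frame = self.ion_pair(50.0)
        res = gbsa_binding_energy(top, frame,
                                  SelectionGroup("p", np.array([0])),
                                  SelectionGroup("i", np.array([1])),
                                  PARAMS)
        assert abs(res.g_binding) < 0.1

    def test_terms_match_independent_direct_summation(self):
        """Every binding term equals a from-scratch recomputation via
        the term formulas on the three separate structures."""
        top, frame = self.ion_pair(0.4)
        prot = SelectionGroup("p", np.array([0]))
        ions = SelectionGroup("i", np.array([1]))
        res = gbsa_binding_energy(top, frame, prot, ions, PARAMS)
        # complex terms
        r_eff = born_radii(top, frame, PARAMS)
        e_gb_c = gb_energy(top.charges, frame, r_eff, PARAMS)
        # separated species: isolated atoms
        e_gb_sep = sum(
            gb_energy([top.charges[i]], np.zeros((1, 3)),
                      [top.radii[i] - PARAMS.offset], PARAMS)
            for i in range(2))
        assert res.e_gb == pytest.approx(e_gb_c - e_gb_sep, abs=1e-6)
        assert res.e_ele == pytest.approx(
            coulomb_energy(top.charges, frame), abs=1e-6)
        assert res.e_vdw == pytest.approx(
            lj_energy(top.sigmas, top.epsilons, frame), abs=1e-6)
        sa_c = sa_energy(top, frame, PARAMS)
        sa_sep = sum(sa_energy(top.subset([i]), frame[[i]], PARAMS)
                     for i in range(2))
        assert res.e_sa == pytest.approx(sa_c - sa_sep, abs=1e-9)
        assert res.g_binding == pytest.approx(
            res.e_gb + res.e_ele + res.e_vdw + res.e_sa, abs=1e-12)

    def test_overlapping_groups_rejected(self):
        top, frame = self.ion_pair(0.4)
        g = SelectionGroup("x", np.array([0, 1]))
        with pytest.raises(AnalysisError):
            gbsa_binding_energy(top, frame, g, g, PARAMS)


class TestMgBoundWaters:
    def test_waters_within_cutoff_ride_with_ion(self):
        n = 1 + 6  # Mg + two 3-atom waters
        top = Topology(
            names=np.array(["MG", "OW", "HW1", "HW2", "OW", "HW1",
                            "HW2"], dtype=object),
            elements=np.array(["MG", "O", "H", "H", "O", "H", "H"],
                              dtype=object),
            masses=np.ones(n),
            resids=np.array([1, 2, 2, 2, 3, 3, 3]),
            resnames=np.array(["MG"] + ["SOL"] * 6, dtype=object),
            chainids=np.array(["I"] + ["W"] * 6, dtype=object))
        frame = np.zeros((n, 3))
        frame[1] = [0.25, 0, 0]   # oxygen inside 0.30 nm shell
        frame[2] = [0.30, 0.05, 0]
        frame[3] = [0.30, -0.05, 0]
        frame[4] = [1.0, 0, 0]    # second water far away
        frame[5] = [1.05, 0.05, 0]
        frame[6] = [1.05, -0.05, 0]
        waters = SelectionGroup("ow", np.array([1, 4]))
        kept = mg_bound_waters(top, frame, 0, waters, cutoff=0.30)
        assert kept.tolist() == [1, 2, 3]


class TestChengPrusoff:
    def assay(self, ic50, name="x"):
        return InhibitionAssay(name, ic50, substrate=200.0, km=20.0,
                               temperature=310.0)

    def test_ki_formula(self):
        a = self.assay(11.0)
        assert cheng_prusoff_ki(a) == pytest.approx(1.0)

    def test_equal_ic50_zero_ddg(self):
        assert cheng_prusoff_ddg(self.assay(5.0), self.assay(5.0)) == \
            pytest.approx(0.0)

    def test_ratio_e_gives_rt(self):
        ddg = cheng_prusoff_ddg(self.assay(np.e), self.assay(1.0))
        assert ddg == pytest.approx(R_GAS * 310.0, rel=1e-12)
        assert ddg == pytest.approx(2.577, abs=1e-3)

    def test_typhimurium_magnitude(self):
        """IC50 pair 0.5 vs 10 uM at 310 K: |DDG| = RT ln 20 = 7.7."""
        mg, hexco = self.assay(0.5, "Mg"), self.assay(10.0, "HexCo")
        ddg = cheng_prusoff_ddg(mg, hexco)
        assert abs(ddg) == pytest.approx(7.7, abs=0.05)
        assert ddg < 0  # the lower-IC50 assay gets the lower RT ln Ki

    def test_mismatched_conditions_rejected(self):
        a = self.assay(1.0)
        b = InhibitionAssay("b", 1.0, substrate=100.0, km=20.0,
                            temperature=310.0)
        with pytest.raises(ParameterError):
            cheng_prusoff_ddg(a, b)

    def test_dg_monotone_in_ki(self):
        assert binding_dg(self.assay(0.5)) < binding_dg(self.assay(10.0))
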
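"""Pair-energy, soft-core and configuration-energy contracts."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lj1264.errors import ConfigurationError, DomainError
from lj1264.potentials import (
    AtomType,
    Configuration,
    PairParams,
    ParameterTable,
    SoftCoreSpec,
    c4_from_polarizability,
    coulomb_pair_energy,
    lj124_pair_energy,
    lj_sigma,
    softcore_vdw,
    total_energy,
    total_forces,
)

P = PairParams(C12=53144.1, C6=145.8, C4=60.0)


class TestLJ124Pair:
    def test_reduces_to_plain_12_6_without_c4(self):
        p = PairParams(C12=1000.0, C6=10.0, C4=0.0)
        for r in (1.5, 2.5, 4.0, 8.0):
            assert lj124_pair_energy(r, p) == pytest.approx(
                p.C12 / r**12 - p.C6 / r**6, rel=1e-14
            )

    def test_minimum_of_12_6_form_is_closed_form(self):
        p = PairParams(C12=53144.1, C6=145.8, C4=0.0)
        r_star = (2.0 * p.C12 / p.C6) ** (1.0 / 6.0)
        assert lj124_pair_energy(r_star, p) == pytest.approx(
            -p.C6**2 / (4.0 * p.C12), rel=1e-12
        )
        # dense scan confirms this is the global minimum
        rs = np.linspace(0.8 * r_star, 3.0 * r_star, 4000)
        es = [lj124_pair_energy(r, p) for r in rs]
        assert min(es) >= -p.C6**2 / (4.0 * p.C12) - 1e-9

    @given(
        c4=st.floats(-500, 500),
        r=st.floats(1.0, 10.0),
    )
    def test_positive_c4_lowers_energy_by_c4_over_r4(self, c4, r):
        base = PairParams(C12=100.0, C6=10.0, C4=0.0)
        shifted = PairParams(C12=100.0, C6=10.0, C4=c4)
        assert lj124_pair_energy(r, shifted) == pytest.approx(
            lj124_pair_energy(r, base) - c4 / r**4, rel=1e-12, abs=1e-12
        )

    @given(scale=st.floats(0.1, 10.0), r=st.floats(1.0, 8.0))
    def test_linearity_in_each_coefficient(self, scale, r):
        p1 = PairParams(C12=200.0, C6=20.0, C4=5.0)
        for attr in ("C12", "C6", "C4"):
            kwargs = {"C12": p1.C12, "C6": p1.C6, "C4": p1.C4}
            kwargs[attr] *= scale
            p2 = PairParams(**kwargs)
            kwargs0 = {"C12": p1.C12, "C6": p1.C6, "C4": p1.C4}
            kwargs0[attr] = 0.0
            p0 = PairParams(**kwargs0)
            e0 = lj124_pair_energy(r, p0)
            e1 = lj124_pair_energy(r, p1)
            e2 = lj124_pair_energy(r, p2)
            assert e2 - e0 == pytest.approx(scale * (e1 - e0), rel=1e-9, abs=1e-9)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(DomainError):
            lj124_pair_energy(0.0, P)
        with pytest.raises(DomainError):
            lj124_pair_energy(-1.0, P)


class TestCoulomb:
    def test_zero_charge_gives_zero(self):
        for r in (0.5, 2.0, 9.0):
            assert coulomb_pair_energy(r, 0.0, 1.0) == 0.0

    def test_one_over_r_scaling(self):
        e1 = coulomb_pair_energy(2.0, 1.0, 1.0)
        e2 = coulomb_pair_energy(4.0, 1.0, 1.0)
        assert e1 == pytest.approx(2.0 * e2, rel=1e-14)

    def test_reference_value(self):
        # +2/−1 pair at k_C/100 Å gives exactly −200 kcal/mol
        assert coulomb_pair_energy(3.320637, 2.0, -1.0, 1.0) == pytest.approx(
            -200.0, abs=1e-9
        )

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            coulomb_pair_energy(-1.0, 1.0, 1.0)
        with pytest.raises(DomainError):
            coulomb_pair_energy(1.0, 1.0, 1.0, dielectric=0.5)


class TestC4FromPolarizability:
    def test_zero_polarizability_gives_zero(self):
        assert c4_from_polarizability(0.0, 2.0) == 0.0

    def test_linearity_and_charge_squared_scaling(self):
        assert c4_from_polarizability(2.0, 1.0) == pytest.approx(
            2.0 * c4_from_polarizability(1.0, 1.0)
        )
        assert c4_from_polarizability(1.0, 2.0) == pytest.approx(
            4.0 * c4_from_polarizability(1.0, 1.0)
        )


class TestSoftCore:
    def test_full_coupling_matches_plain_12_6(self):
        for r in (1.0, 2.0, 3.2, 6.0):
            plain = P.C12 / r**12 - P.C6 / r**6
            assert softcore_vdw(r, SoftCoreSpec(lam=1.0), P) == pytest.approx(
                plain, rel=1e-12, abs=1e-12
            )

    def test_decoupled_is_zero_and_origin_is_finite(self):
        assert softcore_vdw(3.0, SoftCoreSpec(lam=0.0), P) == 0.0
        e0 = softcore_vdw(0.0, SoftCoreSpec(lam=0.5), P)
        assert math.isfinite(e0)

    def test_continuous_in_lambda(self):
        lams = np.linspace(0.0, 1.0, 2001)
        for r in (2.0, 4.0):
            es = np.array(
                [softcore_vdw(r, SoftCoreSpec(lam=float(l)), P) for l in lams]
            )
            assert np.max(np.abs(np.diff(es))) < 0.05  # no jumps on a fine grid
        # deep in the repulsive core the λ-dependence is steep near full
        # coupling but still continuous: U(λ→1) converges to U(1)
        r = 0.5
        e1 = softcore_vdw(r, SoftCoreSpec(lam=1.0), P)
        gaps = [
            abs(softcore_vdw(r, SoftCoreSpec(lam=1.0 - eps), P) - e1) / abs(e1)
            for eps in (1e-4, 1e-7, 1e-10)
        ]
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 1e-5

    def test_sigma_is_zero_crossing(self):
        s = lj_sigma(P)
        assert lj124_pair_energy(s, PairParams(P.C12, P.C6, 0.0)) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_lambda_domain_enforced(self):
        with pytest.raises(DomainError):
            SoftCoreSpec(lam=1.5)


def _three_site_table():
    table = ParameterTable(
        atom_types=[
            AtomType("M", Q=2.0, C12=100.0, C6=10.0),
            AtomType("O", Q=-1.0, C12=400.0, C6=20.0),
        ]
    )
    table.set_pair("M", "O", PairParams(C12=200.0, C6=15.0, C4=30.0))
    return table


class TestTotalEnergy:
    def test_single_particle_is_zero(self):
        cfg = Configuration(np.zeros((1, 3)), ["M"])
        assert total_energy(cfg, _three_site_table()) == 0.0

    def test_two_particle_composition(self):
        table = _three_site_table()
        r = 3.1
        cfg = Configuration([[0, 0, 0], [r, 0, 0]], ["M", "O"])
        expected = lj124_pair_energy(r, table.pair("M", "O")) + coulomb_pair_energy(
            r, 2.0, -1.0
        )
        assert total_energy(cfg, table) == pytest.approx(expected, rel=1e-12)

    def test_equilateral_triangle_is_three_times_pair(self):
        table = _three_site_table()
        a = 3.0
        cfg = Configuration(
            [[0, 0, 0], [a, 0, 0], [a / 2, a * math.sqrt(3) / 2, 0]],
            ["M", "M", "M"],
        )
        pair = lj124_pair_energy(a, table.pair("M", "M")) + coulomb_pair_energy(
            a, 2.0, 2.0
        )
        assert total_energy(cfg, table) == pytest.approx(3.0 * pair, rel=1e-12)

    def test_missing_pair_parameters_named_in_error(self):
        table = ParameterTable(atom_types=[AtomType("M", Q=1.0, C12=1.0, C6=1.0)])
        cfg = Configuration([[0, 0, 0], [3, 0, 0]], ["M", "X"])
        with pytest.raises(ConfigurationError, match="'M'.*'X'|'X'.*'M'"):
            total_energy(cfg, table)

    def test_invariance_under_rigid_motion(self, rng):
        table = _three_site_table()
        coords = rng.uniform(0, 4, (5, 3)) + np.arange(5)[:, None]  # spread out
        types = ["M", "O", "M", "O", "M"]
        cfg = Configuration(coords, types)
        e0 = total_energy(cfg, table)
        # random rotation (QR of a Gaussian matrix) + translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = Configuration(coords @ q.T + np.array([5.0, -3.0, 2.0]), types)
        assert total_energy(moved, table) == pytest.approx(e0, abs=1e-10)

    def test_forces_match_finite_difference(self, rng):
        table = _three_site_table()
        coords = np.array(
            [[0.0, 0, 0], [3.2, 0.3, -0.2], [1.1, 2.9, 0.4], [-2.5, 1.0, 2.0]]
        )
        types = ["M", "O", "M", "O"]
        cfg = Configuration(coords, types)
        analytic = total_forces(cfg, table)
        h = 1e-5
        for i in range(len(coords)):
            for k in range(3):
                cp = coords.copy()
                cm = coords.copy()
                cp[i, k] += h
                cm[i, k] -= h
                num = -(
                    total_energy(Configuration(cp, types), table)
                    - total_energy(Configuration(cm, types), table)
                ) / (2 * h)
                assert num == pytest.approx(
                    analytic[i, k], rel=1e-5, abs=1e-7
                )

    def test_minimum_image_applies_with_box(self):
        table = _three_site_table()
        box = 10.0
        cfg = Configuration([[0.5, 0, 0], [9.5, 0, 0]], ["M", "M"], box=box)
        # minimum-image separation is 1 Å, not 9 Å
        expected = lj124_pair_energy(1.0, table.pair("M", "M")) + coulomb_pair_energy(
            1.0, 2.0, 2.0
        )
        assert total_energy(cfg, table, cutoff=4.0) == pytest.approx(expected)


class TestValidation:
    def test_negative_coefficients_rejected(self):
        with pytest.raises(DomainError):
            PairParams(C12=-1.0, C6=0.0)
        with pytest.raises(DomainError):
            AtomType("bad", C6=-2.0)

    def test_c4_may_be_negative(self):
        assert PairParams(C12=1.0, C6=1.0, C4=-257.0).C4 == -257.0
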
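"""Stokes/Mueller algebra: element forms, chain products, axial angle metric."""

import numpy as np
import pytest

from qpli.mueller import (
    ModeChain,
    StokesVector4,
    aop_circular_difference,
    chain_from_dict,
    chain_to_dict,
    make_element,
    mirror_matrix,
    propagate,
)


def random_physical_state(rng):
    s0 = rng.uniform(0.1, 2.0)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    pol = rng.uniform(0.0, 1.0) * s0
    return StokesVector4(s0, *(pol * direction))


class TestStokesVector:
    def test_rejects_negative_intensity(self):
        with pytest.raises(ValueError, match="S0"):
            StokesVector4(-1.0)

    def test_rejects_overpolarized_state(self):
        with pytest.raises(ValueError, match="non-physical"):
            StokesVector4(1.0, 0.8, 0.8, 0.0)

    def test_circular_states(self):
        assert StokesVector4.circular("right").s3 == 1.0
        assert StokesVector4.circular("left").s3 == -1.0
        with pytest.raises(ValueError, match="handedness"):
            StokesVector4.circular("up")

    def test_aop_range_is_half_open(self):
        # S1 < 0, S2 = 0 gives the branch point: +90 must wrap to -90
        assert StokesVector4(1.0, -0.5, 0.0, 0.0).aop_deg == -90.0


class TestElements:
    def test_full_depolarizer_strips_polarization(self):
        el = make_element("depolarizer", depol_linear=0.0, depol_circular=0.0)
        out = el.apply(StokesVector4(1.0, 0.3, 0.4, 0.5))
        np.testing.assert_allclose(out.as_array(), [1.0, 0.0, 0.0, 0.0], atol=1e-15)

    def test_mirror_flips_helicity_only_on_circular_state(self):
        out = make_element("mirror").apply(StokesVector4(1, 0, 0, 1))
        np.testing.assert_allclose(out.as_array(), [1, 0, 0, -1])

    def test_quarter_wave_retarder_on_rcp_closed_form(self):
        # rows of the retarder matrix at theta=20 deg, delta=pi/2 give
        # (-sin 2theta, cos 2theta, cos delta) acting on S3
        el = make_element("retarder", fast_axis_deg=20.0, retardance_rad=np.pi / 2)
        out = el.apply(StokesVector4.circular("right"))
        np.testing.assert_allclose(
            out.as_array(),
            [1.0, -np.sin(np.deg2rad(40)), np.sin(np.deg2rad(50)), 0.0],
            atol=1e-12,
        )
        np.testing.assert_allclose(out.as_array()[:3], [1.0, -0.6428, 0.7660], atol=5e-5)

    @pytest.mark.parametrize(
        "kind,params,field",
        [
            ("retarder", {"fast_axis_deg": 0.0, "retardance_rad": 7.0}, "retardance_rad"),
            ("depolarizer", {"depol_linear": 1.2, "depol_circular": 0.5}, "depol_linear"),
            ("attenuator", {"transmissivity": -0.1}, "transmissivity"),
        ],
    )
    def test_out_of_range_parameter_names_the_field(self, kind, params, field):
        with pytest.raises(ValueError, match=field):
            make_element(kind, **params)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            make_element("prism")

    def test_mirror_is_involutory(self):
        m = mirror_matrix()
        assert (m @ m == np.eye(4)).all()


class TestPropagate:
    def test_identity_chain_preserves_state(self):
        chain = ModeChain("transmission", [make_element("attenuator", transmissivity=1.0)])
        out = propagate(StokesVector4(1.0, 0.2, 0.0, 0.0), chain)
        np.testing.assert_allclose(out.as_array(), [1.0, 0.2, 0.0, 0.0])

    def test_transmission_aop_is_fast_axis_plus_45(self):
        chain = ModeChain(
            "transmission",
            [make_element("retarder", fast_axis_deg=20.0, retardance_rad=np.pi / 2)],
        )
        assert chain.output().aop_deg == pytest.approx(65.0, abs=1e-12)

    def test_reflectance_chain_shifts_aop_by_90(self):
        chain = ModeChain(
            "reflectance",
            [
                make_element("mirror"),
                make_element("retarder", fast_axis_deg=20.0, retardance_rad=np.pi / 2),
            ],
        )
        assert chain.output().aop_deg == pytest.approx(-25.0, abs=1e-12)
        assert aop_circular_difference(65.0, chain.output().aop_deg) == pytest.approx(90.0)

    def test_mode_chain_mirror_constraints(self):
        ret = make_element("retarder", fast_axis_deg=0.0, retardance_rad=1.0)
        with pytest.raises(ValueError, match="mirror"):
            ModeChain("reflectance", [ret])
        with pytest.raises(ValueError, match="mirror"):
            ModeChain("transmission", [ret, make_element("mirror")])
        with pytest.raises(ValueError, match="at least one"):
            ModeChain("transmission", [])


class TestAopCircularDifference:
    @pytest.mark.parametrize(
        "a,b,expected", [(65, -25, 90), (10, 10, 0), (89, -89, 2), (170, -10, 0), (-90, 90, 0)]
    )
    def test_axial_metric(self, a, b, expected):
        assert aop_circular_difference(a, b) == pytest.approx(expected)

    def test_matches_brute_force_over_branch_shifts(self, rng):
        for _ in range(200):
            a, b = rng.uniform(-720, 720, 2)
            brute = min(
                abs((a - b) + 180 * k) for k in range(-9, 10)
            )
            assert aop_circular_difference(a, b) == pytest.approx(brute, abs=1e-9)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            aop_circular_difference(np.nan, 0.0)


class TestAlgebraProperties:
    def test_retarder_preserves_degree_of_polarization(self, rng):
        for _ in range(300):
            state = random_physical_state(rng)
            el = make_element(
                "retarder",
                fast_axis_deg=rng.uniform(-90, 90),
                retardance_rad=rng.uniform(0, 2 * np.pi - 1e-9),
            )
            out = el.apply(state)
            assert out.dop == pytest.approx(state.dop, abs=1e-12)
            assert out.s0 == pytest.approx(state.s0, abs=1e-12)

    def test_random_chains_preserve_physicality(self, rng):
        kinds = ["retarder", "polarizer", "depolarizer", "attenuator", "mirror"]
        for _ in range(2000):
            state = random_physical_state(rng)
            elements = []
            for _ in range(rng.integers(1, 5)):
                kind = kinds[rng.integers(len(kinds))]
                if kind == "retarder":
                    el = make_element(
                        "retarder",
                        fast_axis_deg=rng.uniform(-90, 90),
                        retardance_rad=rng.uniform(0, 2 * np.pi - 1e-9),
                    )
                elif kind == "polarizer":
                    el = make_element("polarizer", axis_deg=rng.uniform(-90, 90))
                elif kind == "depolarizer":
                    el = make_element(
                        "depolarizer",
                        depol_linear=rng.uniform(0, 1),
                        depol_circular=rng.uniform(0, 1),
                    )
                elif kind == "attenuator":
                    el = make_element("attenuator", transmissivity=rng.uniform(0, 1))
                else:
                    el = make_element("mirror")
                elements.append(el)
            out = elements[0].apply(state)
            for el in elements[1:]:
                out = el.apply(out)  # StokesVector4 validates physicality on construction
            assert out.s0 <= state.s0 * (1 + 1e-9)

    def test_mirror_prepend_shifts_aop_by_exactly_90(self):
        # the mechanism behind the transmission/reflectance mode shift
        for axis in np.arange(0.0, 180.0, 7.5):
            for delta in (0.3, np.pi / 2, 2.8):
                ret = make_element("retarder", fast_axis_deg=axis, retardance_rad=delta)
                t = ModeChain("transmission", [ret]).output().aop_deg
                r = ModeChain("reflectance", [make_element("mirror"), ret]).output().aop_deg
                assert aop_circular_difference(t, r) == pytest.approx(90.0, abs=1e-9)

    def test_handedness_swap_shifts_aop_by_exactly_90(self):
        for axis in np.arange(0.0, 180.0, 7.5):
            for delta in (0.3, np.pi / 2, 2.8):
                ret = make_element("retarder", fast_axis_deg=axis, retardance_rad=delta)
                rcp = ModeChain(
                    "transmission", [ret], input_state=StokesVector4.circular("right")
                ).output().aop_deg
                lcp = ModeChain(
                    "transmission", [ret], input_state=StokesVector4.circular("left")
                ).output().aop_deg
                assert aop_circular_difference(rcp, lcp) == pytest.approx(90.0, abs=1e-9)


class TestSerialization:
    def test_chain_round_trips_through_dict(self):
        chain = ModeChain(
            "reflectance",
            [
                make_element("mirror"),
                make_element("retarder", fast_axis_deg=10.0, retardance_rad=1.2),
                make_element("depolarizer", depol_linear=0.4, depol_circular=0.3),
            ],
        )
        again = chain_from_dict(chain_to_dict(chain))
        np.testing.assert_allclose(again.matrix(), chain.matrix())
        assert again.mode == chain.mode

    def test_unknown_config_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            chain_from_dict({"mode": "transmission", "elements": [], "extra": 1})
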
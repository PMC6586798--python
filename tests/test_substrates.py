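"""Substrate/enzyme structural rules: initiation sites and unit conversion."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from nucleokit.substrates import (
    EnzymeSpec,
    LesionSite,
    SubstrateError,
    SubstrateSpec,
    accessible_ends,
    mass_to_molar,
    molar_to_mass,
)


def _exo3_like(**kw):
    kw.setdefault("max_permissive_overhang", 3)
    return EnzymeSpec(name="exo3like", directionality="3to5", base_rate=0.005, **kw)


class TestAccessibleEnds:
    def test_blunt_duplex_two_sites(self):
        sub = SubstrateSpec(name="blunt80", duplex_length=80)
        sites = accessible_ends(sub, _exo3_like())
        assert len(sites) == 2
        assert all(s.multiplier == 1.0 for s in sites)
        assert {s.site_id for s in sites} == {"top3", "bot3"}

    def test_four_nt_3p_overhang_plus_block_fully_inhibits(self):
        # one 3' end blocked, the other carrying a 4-nt 3' overhang: no entry
        sub = SubstrateSpec(
            name="ovh4", duplex_length=80, blocked_ends={"top3"}, bottom_3p_overhang=4
        )
        assert accessible_ends(sub, _exo3_like()) == []

    def test_20nt_5p_overhang_attenuates_t7_to_half(self):
        sub = SubstrateSpec(
            name="ovh20", duplex_length=80, blocked_ends={"bot5"}, top_5p_overhang=20
        )
        t7 = EnzymeSpec(
            name="t7like",
            directionality="5to3",
            base_rate=0.004,
            overhang_rate_attenuation={20: 0.5},
        )
        sites = accessible_ends(sub, t7)
        assert len(sites) == 1
        assert sites[0].multiplier == 0.5
        assert sites[0].overhang_nt == 20

    def test_two_nt_overhang_permissive(self):
        sub = SubstrateSpec(
            name="ovh2", duplex_length=80, blocked_ends={"top3"}, bottom_3p_overhang=2
        )
        sites = accessible_ends(sub, _exo3_like(overhang_rate_attenuation={2: 0.9}))
        assert len(sites) == 1
        assert sites[0].multiplier == pytest.approx(0.9)

    def test_ss_enzyme_on_blunt_duplex_yields_empty_not_error(self):
        sub = SubstrateSpec(name="blunt", duplex_length=80)
        trex = EnzymeSpec(
            name="sslike", directionality="ss_only", base_rate=1e-4, initiates_at={"ss_terminus"}
        )
        assert accessible_ends(sub, trex) == []

    def test_nick_site_geometry(self):
        sub = SubstrateSpec(
            name="nicked", duplex_length=80, blocked_ends={"top3", "bot3"}, nicks=[("top", 60)]
        )
        enz = _exo3_like(initiates_at={"blunt_end", "overhang_end", "nick"})
        sites = accessible_ends(sub, enz)
        assert [s.kind for s in sites] == ["nick"]
        # 3'->5' on the top strand resects leftward from the cut
        assert sites[0].entry == 59 and sites[0].direction == -1

    def test_polymerase_primer_terminus(self):
        sub = SubstrateSpec(
            name="pt", duplex_length=80, is_primer_template=True, primer_length=20
        )
        kf = EnzymeSpec(name="kf", directionality="polymerase", base_rate=0.05)
        sites = accessible_ends(sub, kf)
        assert len(sites) == 1 and sites[0].kind == "primer" and sites[0].entry == 20


@st.composite
def _substrate_and_enzyme(draw):
    L = draw(st.integers(min_value=10, max_value=120))
    overs = [draw(st.integers(min_value=0, max_value=6)) for _ in range(4)]
    ends = draw(st.sets(st.sampled_from(["top5", "top3", "bot5", "bot3"])))
    sub = SubstrateSpec(
        name="rand",
        duplex_length=L,
        top_5p_overhang=overs[0],
        top_3p_overhang=overs[1],
        bottom_5p_overhang=overs[2],
        bottom_3p_overhang=overs[3],
        blocked_ends=ends,
    )
    direction = draw(st.sampled_from(["3to5", "5to3"]))
    mpo = draw(st.one_of(st.none(), st.integers(min_value=0, max_value=5)))
    enz = EnzymeSpec(name="rand_e", directionality=direction, base_rate=1.0, max_permissive_overhang=mpo)
    extra = draw(st.sampled_from(["top5", "top3", "bot5", "bot3"]))
    return sub, enz, extra


class TestStructuralInvariants:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(_substrate_and_enzyme())
    def test_blocking_is_monotone(self, case):
        """Adding an end to blocked_ends never creates initiation sites."""
        sub, enz, extra = case
        before = accessible_ends(sub, enz)
        after = accessible_ends(sub, enz, blocked_ends=sub.blocked_ends | {extra})
        assert len(after) <= len(before)
        assert {s.site_id for s in after} <= {s.site_id for s in before}

    def test_attenuation_never_exceeds_one(self):
        with pytest.raises(SubstrateError):
            EnzymeSpec(
                name="bad",
                directionality="5to3",
                base_rate=1.0,
                overhang_rate_attenuation={10: 1.2},
            )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=30))
    def test_overhang_multiplier_at_most_one(self, length):
        enz = EnzymeSpec(
            name="e",
            directionality="5to3",
            base_rate=1.0,
            overhang_rate_attenuation={5: 0.5, 20: 0.1},
        )
        m = enz.overhang_multiplier(length)
        assert m is None or 0 < m <= 1


class TestValidation:
    def test_unknown_blocked_end(self):
        with pytest.raises(SubstrateError):
            SubstrateSpec(name="bad", duplex_length=10, blocked_ends={"left"})

    def test_nick_outside_strand(self):
        with pytest.raises(SubstrateError):
            SubstrateSpec(name="bad", duplex_length=10, nicks=[("top", 50)])

    def test_nick_inside_gap(self):
        with pytest.raises(SubstrateError):
            SubstrateSpec(
                name="bad", duplex_length=40, nicks=[("top", 21)], gaps=[("top", 20, 3)]
            )

    def test_negative_overhang(self):
        with pytest.raises(SubstrateError):
            SubstrateSpec(name="bad", duplex_length=10, top_3p_overhang=-1)

    def test_lesion_multiplier_positive(self):
        with pytest.raises(SubstrateError):
            LesionSite(strand="both", position=5, kind="mismatch_AC", rate_multiplier=0.0).validate()


class TestConcentrationConversion:
    def test_80bp_duplex_at_50nM(self):
        sub = SubstrateSpec(name="d80", duplex_length=80)
        assert molar_to_mass(sub, 50.0) == pytest.approx(2.6)

    def test_zero_molar(self):
        sub = SubstrateSpec(name="d80", duplex_length=80)
        assert molar_to_mass(sub, 0.0) == 0.0

    def test_20nt_ssDNA_at_50nM(self):
        sub = SubstrateSpec(name="ss20", nucleic_kind="ssDNA", ss_length=20)
        assert molar_to_mass(sub, 50.0) == pytest.approx(0.33)

    def test_negative_input_rejected(self):
        sub = SubstrateSpec(name="d80", duplex_length=80)
        with pytest.raises(SubstrateError):
            molar_to_mass(sub, -1.0)
        with pytest.raises(SubstrateError):
            mass_to_molar(sub, -1.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.floats(min_value=1e-3, max_value=1e4, allow_nan=False),
        st.integers(min_value=1, max_value=500),
    )
    def test_round_trip_bijection(self, molar, L):
        sub = SubstrateSpec(name="d", duplex_length=L)
        back = mass_to_molar(sub, molar_to_mass(sub, molar))
        assert math.isclose(back, molar, rel_tol=1e-12)
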
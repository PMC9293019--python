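"""Landscape containers and dual-cycle network construction."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualcycle.landscape import (
    FreeEnergyLandscape,
    LandscapeError,
    StationaryPoint,
    StereoLabel,
)
from dualcycle.network import (
    NetworkConstructionError,
    NetworkOptions,
    Species,
    build_dual_cycle_network,
    validate_network,
)
from dualcycle.synth import ChannelSpec, LandscapeSpec, generate_landscape


def make_landscape(channels, reaction_type="aldol"):
    """Landscape from (cycle, conformer, faces, config, barrier) tuples."""
    enamine_g = {}
    complex_g = {}
    chans = []
    for cyc, conf, faces, config, dg in channels:
        enamine_g.setdefault((cyc, conf), 0.0)
        complex_g.setdefault((cyc, conf), 1.0)
        chans.append(ChannelSpec(cyc, conf, faces, config, dg))
    return generate_landscape(LandscapeSpec(
        reaction_type=reaction_type, enamine_g=enamine_g,
        complex_g=complex_g, channels=chans,
    ))


class TestStereoLabel:
    def test_mirror_is_involution(self):
        lbl = StereoLabel("Si,Si", "2R,1'S", topology="lk")
        assert lbl.mirrored().mirrored() == lbl
        assert lbl.mirrored().product_config == "2S,1'R"
        assert lbl.mirrored().face_pair == "Re,Re"

    def test_diastereo_class_by_reaction_family(self):
        major = StereoLabel("Si,Si", "2R,1'S")
        minor = StereoLabel("Si,Re", "2R,1'R")
        assert major.diastereo_class("aldol") == "anti"
        assert major.diastereo_class("michael") == "syn"
        assert minor.diastereo_class("aldol") == "syn"
        assert minor.diastereo_class("michael") == "anti"

    def test_unknown_tokens_rejected(self):
        with pytest.raises(LandscapeError):
            StereoLabel("Si,Si", "3R,1'S")
        with pytest.raises(LandscapeError):
            StereoLabel("Si,Xy", "2R,1'S")


class TestLandscapeValidation:
    def test_duplicate_names_rejected(self):
        pts = [
            StationaryPoint("X", "intermediate", 0.0, "A", "proximal"),
            StationaryPoint("X", "reactive_complex", 1.0, "A", "proximal"),
            StationaryPoint("T", "transition_state", 14.0, "A", "proximal",
                            stereo=StereoLabel("Si,Si", "2R,1'S")),
        ]
        with pytest.raises(LandscapeError, match="duplicate"):
            FreeEnergyLandscape("aldol", pts)

    def test_transition_state_requires_stereo(self):
        with pytest.raises(LandscapeError, match="stereo"):
            StationaryPoint("TS", "transition_state", 14.0, "A", "proximal")

    def test_unknown_role_rejected(self):
        with pytest.raises(LandscapeError):
            StationaryPoint("X", "saddle", 0.0)


class TestBuildDualCycleNetwork:
    def test_channel_and_product_counts(self):
        # 2 cycles, 2 conformers each; 4 stereochannels in A, 2 in B
        ls = make_landscape([
            ("A", "proximal", "Si,Si", "2R,1'S", 13.0),
            ("A", "proximal", "Re,Re", "2S,1'R", 15.0),
            ("A", "distal", "Si,Re", "2R,1'R", 14.0),
            ("A", "distal", "Re,Si", "2S,1'S", 16.0),
            ("B", "proximal", "Si,Si", "2R,1'S", 12.5),
            ("B", "distal", "Si,Re", "2R,1'R", 13.5),
        ])
        net = build_dual_cycle_network(ls)
        cc = [r for r in net.reactions if r.kind == "cc"]
        products = {ch.product_species for ch in net.channels}
        assert len(cc) == 6
        assert len(products) == 6
        assert all(ch.stereo is not None for ch in net.channels)
        assert validate_network(net).passed

    def test_minimal_single_channel_topology(self):
        ls = make_landscape([("A", "proximal", "Si,Si", "2R,1'S", 15.0)])
        net = build_dual_cycle_network(ls)
        kinds = [r.kind for r in net.reactions]
        assert kinds.count("cc") == 1
        # one complete turnover path: activate, form enamine, bind, C-C, release
        for kind in ("protonation", "enamine", "association", "cc", "hydrolysis"):
            assert kind in kinds
        assert validate_network(net).passed

    def test_michael_topology_mirrors_aldol(self):
        ls = make_landscape(
            [("A", "proximal", "Re,Si", "2R,1'S", 14.0)], reaction_type="michael"
        )
        net = build_dual_cycle_network(ls)
        assert net.reaction_type == "michael"
        assert net.channels[0].stereo.diastereo_class("michael") == "syn"
        assert validate_network(net).passed

    def test_ts_without_reactive_complex_rejected(self):
        pts = [
            StationaryPoint("EN", "intermediate", 0.0, "A", "proximal"),
            StationaryPoint("TS", "transition_state", 14.0, "A", "proximal",
                            stereo=StereoLabel("Si,Si", "2R,1'S")),
        ]
        ls = FreeEnergyLandscape("aldol", pts)
        with pytest.raises(NetworkConstructionError, match="reactive complex"):
            build_dual_cycle_network(ls)

    def test_cycle_without_enamine_rejected(self):
        pts = [
            StationaryPoint("RC", "reactive_complex", 1.0, "A", "proximal"),
            StationaryPoint("TS", "transition_state", 14.0, "A", "proximal",
                            stereo=StereoLabel("Si,Si", "2R,1'S")),
        ]
        ls = FreeEnergyLandscape("aldol", pts)
        with pytest.raises(NetworkConstructionError, match="enamine"):
            build_dual_cycle_network(ls)

    def test_ts_below_complex_rejected(self):
        ls = make_landscape([("A", "proximal", "Si,Si", "2R,1'S", 15.0)])
        pts = [
            p if p.role != "transition_state"
            else StationaryPoint(p.name, p.role, -5.0, p.cycle, p.conformer, p.stereo)
            for p in ls.points
        ]
        with pytest.raises(NetworkConstructionError, match="below"):
            build_dual_cycle_network(FreeEnergyLandscape("aldol", pts))

    def test_catalyst_tag_conserved_in_every_reaction(self):
        ls = make_landscape([
            ("A", "proximal", "Si,Si", "2R,1'S", 13.0),
            ("B", "distal", "Re,Re", "2S,1'R", 14.0),
        ])
        net = build_dual_cycle_network(ls)
        for rxn in net.reactions:
            lhs = sum(n * net.species[s].tag("catalyst") for s, n in rxn.reactants.items())
            rhs = sum(n * net.species[s].tag("catalyst") for s, n in rxn.products.items())
            assert lhs == rhs

    @given(
        n_a=st.integers(min_value=1, max_value=4),
        n_b=st.integers(min_value=0, max_value=2),
        two_conf=st.booleans(),
    )
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_reaction_count_formula(self, n_a, n_b, two_conf):
        """count = per-cycle overhead (protonation + enamines + flips + bindings)
        plus two reactions (C-C and hydrolysis) per transition state."""
        configs = ["2R,1'S", "2S,1'R", "2R,1'R", "2S,1'S"]
        faces = ["Si,Si", "Re,Re", "Si,Re", "Re,Si"]
        chans = [("A", "proximal", faces[i], configs[i], 13.0 + i) for i in range(n_a)]
        conf_b = "distal" if two_conf else "proximal"
        chans += [("B", conf_b, faces[i], configs[i], 13.0 + i) for i in range(n_b)]
        if not chans:
            return
        ls = make_landscape(chans)
        net = build_dual_cycle_network(ls)
        n_cycles = len({c for c, *_ in chans})
        conf_pairs = {(c, conf) for c, conf, *_ in chans}
        n_ts = len(chans)
        # per cycle: 1 protonation + (#conformers) enamine + (#conformers-1)
        # flips + (#complexes) associations; here one complex per conformer
        overhead = n_cycles + len(conf_pairs) + sum(
            len([cf for cy, cf in conf_pairs if cy == c]) - 1
            for c in {c for c, *_ in chans}
        ) + len(conf_pairs)
        assert len(net.reactions) == overhead + 2 * n_ts
        assert validate_network(net).passed


class TestValidateNetwork:
    def test_imbalance_flagged(self):
        ls = make_landscape([("A", "proximal", "Si,Si", "2R,1'S", 15.0)])
        net = build_dual_cycle_network(ls)
        # corrupt a species: drop the catalyst tag from the protonated form
        net.species["catH_A"] = Species("catH_A", {"acid_proton": 1})
        diag = validate_network(net)
        assert not diag.passed
        assert any(tag == "catalyst" for (_, _, tag, _, _) in diag.imbalanced)

    def test_unreachable_species_flagged(self):
        ls = make_landscape([("A", "proximal", "Si,Si", "2R,1'S", 15.0)])
        net = build_dual_cycle_network(ls)
        net.species["orphan"] = Species("orphan", {})
        diag = validate_network(net)
        assert diag.unreachable == ["orphan"]
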
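import pytest

from metaecoflux.core import (
    Compartment,
    Flow,
    Orientation,
    Role,
    Significance,
    ValidationError,
    build_network,
)
from metaecoflux.significance import (
    LandscapeClass,
    SignificanceConfig,
    classify_landscape_system,
    flag_significance,
)

EXPECTED_INSIGNIFICANT = {
    ("External", "forest", "precipitation"),
    ("External", "wetland", "precipitation"),
    ("wetland", "surface_waters", "litter"),
    ("wetland", "surface_waters", "DIC_runoff"),
    ("wetland", "External", "CH4"),
}


def flags(net):
    return {
        f.key: f.significance
        for f in flag_significance(net, SignificanceConfig()).flows
    }


class TestFlagging:
    def test_nhld_insignificant_set(self, nhld):
        """The 1% rule singles out exactly the five negligible fluxes."""
        got = {
            k for k, v in flags(nhld).items() if v is Significance.INSIGNIFICANT
        }
        assert got == EXPECTED_INSIGNIFICANT

    def test_small_flux_significant_to_small_ecosystem(self, nhld):
        # forest DIC runoff (10) is below 1% of the forest's activity but
        # above 1% of the surface waters' — the recipient depends on it
        assert flags(nhld)[
            ("forest", "surface_waters", "DIC_runoff")
        ] is Significance.SIGNIFICANT

    def test_self_flows_always_significant(self, nhld):
        assert flags(nhld)[
            ("surface_waters", "surface_waters", "accumulation")
        ] is Significance.SIGNIFICANT

    def test_zero_magnitude_flow_insignificant(self):
        net = build_network(
            [Compartment(id="a"), Compartment(id="b")],
            [
                Flow(source="a", target="b", best=0.0),
                Flow(source="b", target="a", best=100.0),
            ],
        )
        flagged = flag_significance(net)
        assert flagged.flows[0].significance is Significance.INSIGNIFICANT

    def test_idempotent(self, nhld):
        once = flag_significance(nhld)
        twice = flag_significance(once)
        assert once.flows == twice.flows

    @pytest.mark.parametrize("factor", [1.5, 10.0, 1e4])
    def test_inflating_one_flow_never_flips_it_insignificant(self, nhld, factor):
        base = flags(nhld)
        for key, sig in base.items():
            if sig is not Significance.SIGNIFICANT:
                continue
            inflated = nhld.with_flows(
                Flow(
                    source=f.source,
                    target=f.target,
                    process=f.process,
                    orientation=f.orientation,
                    best=f.best * factor if f.key == key else f.best,
                )
                for f in nhld.flows
            )
            assert flags(inflated)[key] is Significance.SIGNIFICANT

    def test_ratio_extremes(self, nhld):
        tiny = flag_significance(nhld, SignificanceConfig(ratio=1e-12))
        assert all(
            f.significance is Significance.SIGNIFICANT
            for f in tiny.flows
            if abs(f.best) > 0
        )
        huge = flag_significance(nhld, SignificanceConfig(ratio=0.999))
        kept = [
            f
            for f in huge.flows
            if not f.is_self_flow and f.significance is Significance.SIGNIFICANT
        ]
        # only fluxes comparable to a whole ecosystem's throughput survive
        assert all(abs(f.best) >= 100.0 for f in kept)

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValidationError):
            SignificanceConfig(ratio=0.0)
        with pytest.raises(ValidationError):
            SignificanceConfig(ratio=1.0)


def toy(flows, n=3):
    comps = [Compartment(id=f"e{i}", role=Role.INTERNAL) for i in range(n)]
    comps.append(Compartment(id="out", role=Role.EXTERIOR))
    return build_network(comps, flows)


class TestClassification:
    def test_nhld_is_fragmental(self, nhld):
        flagged = flag_significance(nhld)
        assert classify_landscape_system(flagged) is LandscapeClass.FRAGMENTAL

    def test_closed_interconnected_is_systemic(self):
        net = toy(
            [
                Flow(source="e0", target="e1", best=5.0),
                Flow(source="e1", target="e2", best=5.0),
                Flow(source="e2", target="e0", best=5.0),
            ]
        )
        assert (
            classify_landscape_system(flag_significance(net))
            is LandscapeClass.SYSTEMIC
        )

    def test_isolated_ecosystems_are_omnidirectionally_discrete(self):
        # ecosystems only cycle carbon internally; nothing moves between them
        net = toy(
            [
                Flow(source="e0", target="e0", process="accumulation", best=5.0),
                Flow(source="e1", target="e1", process="accumulation", best=5.0),
                Flow(source="e2", target="e2", process="sediment", best=5.0),
            ]
        )
        flagged = flag_significance(net)
        assert (
            classify_landscape_system(flagged)
            is LandscapeClass.OMNIDIRECTIONALLY_DISCRETE
        )

    def test_vertical_only_connection_is_laterally_discrete(self):
        # each ecosystem exchanges with the shared atmosphere, none laterally
        net = toy(
            [
                Flow(
                    source="out",
                    target="e0",
                    orientation=Orientation.VERTICAL,
                    best=5.0,
                ),
                Flow(
                    source="out",
                    target="e1",
                    orientation=Orientation.VERTICAL,
                    best=5.0,
                ),
                Flow(
                    source="e2",
                    target="out",
                    orientation=Orientation.VERTICAL,
                    best=5.0,
                ),
            ]
        )
        assert (
            classify_landscape_system(flag_significance(net))
            is LandscapeClass.LATERALLY_DISCRETE
        )

    def test_unflagged_network_rejected(self, nhld):
        with pytest.raises(ValidationError, match="flag_significance"):
            classify_landscape_system(nhld)
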
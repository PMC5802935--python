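import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaecoflux.core import Compartment, Flow, ValidationError, build_network
from metaecoflux.ena import (
    ami,
    ascendency,
    capacity,
    redundancy,
    report,
    tst,
)
from metaecoflux.synth import GeneratorConfig, generate_network

from ._oracle import brute_force_indices, network_to_matrix
from .conftest import ring_network, uniform_network_with_self_loops


class TestClosedForms:
    @pytest.mark.parametrize("n", range(2, 9))
    def test_ring_ami_is_log2_n(self, n):
        """Each flow fully determines its successor: AMI = log2(n) bits."""
        net = ring_network(n)
        assert ami(net) == pytest.approx(math.log2(n), rel=1e-12)

    @pytest.mark.parametrize("n", range(2, 9))
    def test_ring_is_maximally_constrained(self, n):
        """A single pathway has no parallel capacity: R = 0, A = C."""
        net = ring_network(n)
        assert redundancy(net) == pytest.approx(0.0, abs=1e-9)
        assert ascendency(net) == pytest.approx(n * math.log2(n), rel=1e-12)
        # the throughflow-diversity bound is tight here too
        assert redundancy(net, form="throughflow") == pytest.approx(0.0, abs=1e-9)

    def test_ring4_reference_values(self, ring4):
        assert tst(ring4) == pytest.approx(4.0)
        assert ami(ring4) == pytest.approx(2.0)
        assert ascendency(ring4) == pytest.approx(8.0)
        assert capacity(ring4) == pytest.approx(8.0)

    @pytest.mark.parametrize("n", range(2, 9))
    def test_uniform_network_with_self_loops_has_zero_ami(self, n):
        net = uniform_network_with_self_loops(n)
        assert ami(net) == pytest.approx(0.0, abs=1e-12)
        # all capacity is redundancy
        assert redundancy(net) == pytest.approx(capacity(net), rel=1e-12)

    def test_single_flow_has_no_organisation(self):
        net = build_network(
            [Compartment(id="a"), Compartment(id="b")],
            [Flow(source="a", target="b", best=5.0)],
        )
        assert ascendency(net) == pytest.approx(0.0, abs=1e-12)
        assert capacity(net) == pytest.approx(0.0, abs=1e-12)
        assert capacity(net, form="throughflow") == pytest.approx(0.0, abs=1e-12)

    def test_empty_network_tst_zero_and_indices_undefined(self):
        net = build_network([], [])
        assert tst(net) == 0.0
        with pytest.raises(ValidationError):
            ami(net)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(100))
    def test_indices_match_brute_force(self, seed):
        """Production indices equal a literal double-loop evaluation."""
        cfg = GeneratorConfig(
            n=3 + seed % 6,
            connectance=0.3 + 0.1 * (seed % 7),
            sigma=0.5 + 0.25 * (seed % 3),
            seed=seed,
            balanced=(seed % 4 == 0),
        )
        net = generate_network(cfg)
        expected = brute_force_indices(network_to_matrix(net))
        assert tst(net) == pytest.approx(expected["tst"], rel=1e-9)
        assert ami(net) == pytest.approx(expected["ami"], rel=1e-9, abs=1e-12)
        assert ascendency(net) == pytest.approx(
            expected["ascendency"], rel=1e-9, abs=1e-12
        )
        assert capacity(net, form="flow") == pytest.approx(
            expected["capacity_flow"], rel=1e-9, abs=1e-12
        )
        assert capacity(net, form="throughflow") == pytest.approx(
            expected["capacity_throughflow"], rel=1e-9, abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(0, 100, 7))
    def test_log_base_conversion(self, seed):
        net = generate_network(GeneratorConfig(n=5, connectance=0.5, seed=seed))
        assert ami(net, log_base=math.e) == pytest.approx(
            ami(net, log_base=2) * math.log(2), rel=1e-9
        )


class TestProperties:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        c=st.floats(1e-3, 1e3, allow_nan=False, allow_infinity=False),
    )
    def test_scale_equivariance(self, seed, c):
        """Scaling all flows by c scales TST/A/C/R by c; AMI is unchanged."""
        net = generate_network(GeneratorConfig(n=5, connectance=0.6, seed=seed))
        scaled = net.with_flows(
            Flow(
                source=f.source,
                target=f.target,
                process=f.process,
                orientation=f.orientation,
                best=c * f.best,
            )
            for f in net.flows
        )
        assert tst(scaled) == pytest.approx(c * tst(net), rel=1e-9)
        assert ami(scaled) == pytest.approx(ami(net), rel=1e-9, abs=1e-12)
        for form in ("flow", "throughflow"):
            assert capacity(scaled, form=form) == pytest.approx(
                c * capacity(net, form=form), rel=1e-9
            )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_permutation_invariance(self, seed):
        net = generate_network(GeneratorConfig(n=6, connectance=0.5, seed=seed))
        n = len(net.compartments)
        relabel = {f"c{i}": f"z{(i * 5 + 3) % n}" for i in range(n)}
        permuted = build_network(
            [Compartment(id=relabel[c.id], role=c.role) for c in net.compartments],
            [
                Flow(
                    source=relabel[f.source],
                    target=relabel[f.target],
                    process=f.process,
                    orientation=f.orientation,
                    best=f.best,
                )
                for f in net.flows
            ],
        )
        assert tst(permuted) == pytest.approx(tst(net), rel=1e-12)
        assert ami(permuted) == pytest.approx(ami(net), rel=1e-12, abs=1e-12)
        assert capacity(permuted) == pytest.approx(capacity(net), rel=1e-12)

    @pytest.mark.parametrize("seed", range(100))
    def test_ascendency_bounded_by_both_capacity_forms(self, seed):
        net = generate_network(
            GeneratorConfig(n=4 + seed % 5, connectance=0.4, seed=1000 + seed)
        )
        a = ascendency(net)
        assert 0.0 <= a <= capacity(net, form="flow") + 1e-9
        assert a <= capacity(net, form="throughflow") + 1e-9

    @pytest.mark.parametrize("form", ["flow", "throughflow"])
    def test_report_identities(self, form):
        net = generate_network(GeneratorConfig(n=6, connectance=0.5, seed=3))
        r = report(net, total_stock=1000.0, capacity_form=form)
        assert r.ascendency == pytest.approx(r.tst * r.ami, rel=1e-12)
        assert r.ascendency + r.redundancy == pytest.approx(r.capacity, rel=1e-12)
        assert r.ascendency_ratio + r.resilience_ratio == pytest.approx(1.0)
        assert r.activity_ratio == pytest.approx(r.tst / 1000.0)

    def test_ring_report_resilience_zero(self, ring4):
        assert report(ring4).resilience_ratio == pytest.approx(0.0, abs=1e-12)
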
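"""Serial, hierarchical, and conditional composites versus direct composition."""

import random

import pytest

from kocompose.activator import Activator
from kocompose.composition import (
    ModelReference,
    make_conditional_executive,
    make_serial_executive,
    oracle_compose,
)
from kocompose.ko_package import PersistentId

from conftest import make_toy_package

DOUBLE = "def run(inputs):\n    return {'value': inputs['value'] * 2}\n"
ADD_ONE = "def run(inputs):\n    return {'value': inputs['value'] + 1}\n"
SQUARE_MOD = "def run(inputs):\n    return {'value': inputs['value'] ** 2 % 97}\n"

double_fn = lambda r: {"value": r["value"] * 2}  # noqa: E731
add_one_fn = lambda r: {"value": r["value"] + 1}  # noqa: E731
square_fn = lambda r: {"value": r["value"] ** 2 % 97}  # noqa: E731


def _activate_toys(activator: Activator) -> dict[str, str]:
    keys = {}
    for name, source in [("double", DOUBLE), ("addone", ADD_ONE), ("square", SQUARE_MOD)]:
        pkg = make_toy_package(name, source)
        activator.activate(pkg)
        keys[name] = pkg.endpoint_key
    return keys


def _run(activator: Activator, pkg, payload):
    activator.activate(pkg)
    response = activator.route(pkg.endpoint_key, "post", payload)
    assert response.status == "ok", response.body
    return response.body["result"]


class TestSerial:
    def test_single_reference_executive_equals_the_model(self, activator):
        keys = _activate_toys(activator)
        execu = make_serial_executive(
            [ModelReference(keys["double"])], PersistentId("12345", "exec-one", "1.0.0")
        )
        assert _run(activator, execu, {"value": 5}) == {"value": 10}

    def test_order_matters(self, activator):
        keys = _activate_toys(activator)
        fwd = make_serial_executive(
            [ModelReference(keys["double"]), ModelReference(keys["addone"])],
            PersistentId("12345", "exec-fwd", "1.0.0"),
        )
        rev = make_serial_executive(
            [ModelReference(keys["addone"]), ModelReference(keys["double"])],
            PersistentId("12345", "exec-rev", "1.0.0"),
        )
        assert _run(activator, fwd, {"value": 5}) == {"value": 11}
        assert _run(activator, rev, {"value": 5}) == {"value": 12}

    def test_three_model_chain_matches_oracle_on_random_inputs(self, activator):
        keys = _activate_toys(activator)
        chain = make_serial_executive(
            [ModelReference(keys[n]) for n in ("double", "addone", "square")],
            PersistentId("12345", "exec-chain", "1.0.0"),
        )
        activator.activate(chain)
        rng = random.Random(4)
        for _ in range(100):
            record = {"value": rng.randint(-1000, 1000)}
            via_gateway = activator.route(chain.endpoint_key, "post", record)
            expected = oracle_compose([double_fn, add_one_fn, square_fn], record)
            assert via_gateway.body["result"] == expected

    def test_empty_reference_list_rejected(self):
        with pytest.raises(ValueError):
            make_serial_executive([], PersistentId("12345", "exec-empty", "1.0.0"))

    def test_input_mapping_renames_fields(self, activator):
        consumer = make_toy_package("consumer", "def run(inputs):\n    return {'value': inputs['x']}\n")
        activator.activate(consumer)
        execu = make_serial_executive(
            [ModelReference(consumer.endpoint_key, input_mapping={"value": "x"})],
            PersistentId("12345", "exec-map", "1.0.0"),
        )
        assert _run(activator, execu, {"value": 9}) == {"value": 9}


class TestOracle:
    def test_identity_cases(self):
        assert oracle_compose([double_fn], {"value": 3}) == {"value": 6}
        assert oracle_compose([], {"value": 3}) == {"value": 3}


class TestHierarchical:
    def test_executive_of_executives_equals_flattened_chain(self, activator):
        keys = _activate_toys(activator)
        inner = make_serial_executive(
            [ModelReference(keys["double"]), ModelReference(keys["addone"])],
            PersistentId("12345", "exec-inner", "1.0.0"),
        )
        activator.activate(inner)
        outer = make_serial_executive(
            [ModelReference(inner.endpoint_key), ModelReference(keys["square"])],
            PersistentId("12345", "exec-outer", "1.0.0"),
        )
        flat = make_serial_executive(
            [ModelReference(keys[n]) for n in ("double", "addone", "square")],
            PersistentId("12345", "exec-flat", "1.0.0"),
        )
        activator.activate(outer)
        activator.activate(flat)
        for value in range(-20, 21, 7):
            hier = activator.route(outer.endpoint_key, "post", {"value": value})
            serial = activator.route(flat.endpoint_key, "post", {"value": value})
            assert hier.body["result"] == serial.body["result"]

    def test_deactivating_executive_leaves_callees_active(self, activator):
        keys = _activate_toys(activator)
        execu = make_serial_executive(
            [ModelReference(keys["double"])], PersistentId("12345", "exec-drop", "1.0.0")
        )
        activator.activate(execu)
        before = set(activator.context.entries)
        activator.deactivate(execu.endpoint_key)
        assert set(activator.context.entries) == before - {execu.endpoint_key}
        assert activator.route(keys["double"], "post", {"value": 1}).status == "ok"


class TestConditional:
    def test_exactly_one_branch_engaged(self, activator):
        keys = _activate_toys(activator)
        execu = make_conditional_executive(
            "flag",
            {True: ModelReference(keys["double"]), False: ModelReference(keys["addone"])},
            PersistentId("12345", "exec-cond", "1.0.0"),
        )
        activator.activate(execu)
        activator.call_log.clear()
        response = activator.route(execu.endpoint_key, "post", {"flag": True, "value": 4})
        assert response.body["result"] == {"value": 8}
        invoked = [key for key, _ in activator.call_log]
        assert invoked.count(keys["double"]) == 1
        assert invoked.count(keys["addone"]) == 0

    def test_unmapped_value_without_default_is_model_error(self, activator):
        keys = _activate_toys(activator)
        execu = make_conditional_executive(
            "flag",
            {True: ModelReference(keys["double"])},
            PersistentId("12345", "exec-nodefault", "1.0.0"),
        )
        activator.activate(execu)
        response = activator.route(execu.endpoint_key, "post", {"flag": "other", "value": 4})
        assert response.status == "model_error"
        assert "no branch" in response.body["error"]

    def test_branch_counts_match_predicate_distribution(self, activator):
        keys = _activate_toys(activator)
        execu = make_conditional_executive(
            "flag",
            {True: ModelReference(keys["double"]), False: ModelReference(keys["addone"])},
            PersistentId("12345", "exec-count", "1.0.0"),
        )
        activator.activate(execu)
        rng = random.Random(9)
        flags = [rng.random() < 0.3 for _ in range(1000)]
        activator.call_log.clear()
        for flag in flags:
            activator.route(execu.endpoint_key, "post", {"flag": flag, "value": 1})
        invoked = [key for key, _ in activator.call_log]
        assert invoked.count(keys["double"]) == sum(flags)
        assert invoked.count(keys["addone"]) == len(flags) - sum(flags)
        # per request: executive + exactly one branch
        assert len(invoked) == 2 * len(flags)

    def test_mixed_three_level_tree_matches_direct_evaluation(self, activator):
        """serial( conditional( serial(double,addone) | square ), addone ) vs plain calls."""
        keys = _activate_toys(activator)
        inner_serial = make_serial_executive(
            [ModelReference(keys["double"]), ModelReference(keys["addone"])],
            PersistentId("12345", "mix-serial", "1.0.0"),
        )
        activator.activate(inner_serial)
        cond = make_conditional_executive(
            "flag",
            {
                True: ModelReference(inner_serial.endpoint_key),
                False: ModelReference(keys["square"]),
            },
            PersistentId("12345", "mix-cond", "1.0.0"),
        )
        activator.activate(cond)
        top = make_serial_executive(
            [ModelReference(cond.endpoint_key), ModelReference(keys["addone"])],
            PersistentId("12345", "mix-top", "1.0.0"),
        )
        activator.activate(top)
        rng = random.Random(23)
        for _ in range(50):
            record = {"flag": rng.random() < 0.5, "value": rng.randint(-50, 50)}
            got = activator.route(top.endpoint_key, "post", dict(record))
            if record["flag"]:
                mid = add_one_fn(double_fn(record))
            else:
                mid = square_fn(record)
            expected = add_one_fn(mid)
            assert got.body["result"] == expected
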
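"""Composite models via Executive Submodels.

Three composite kinds are supported — serial, hierarchical, conditional —
plus mixtures. An *executive* is an ordinary KO whose payload encodes the
procedural composition logic: which other deployed models to call, in what
order, under what conditions. Because executives are generated as plain
source payloads, composites remain inspectable and shippable like any other
package, and hierarchy needs no special casing: a serial executive whose
references include another executive *is* a hierarchical composite.

``oracle_compose`` is the gateway-free reference used in equivalence tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Callable, Iterable, Mapping, Sequence

from kocompose.ko_package import (
    DeploymentSpec,
    KnowledgeObjectPackage,
    KoMetadata,
    PersistentId,
    ServiceSpec,
)

__all__ = [
    "CompositionKind",
    "ModelReference",
    "make_executive_package",
    "make_serial_executive",
    "make_conditional_executive",
    "oracle_compose",
]

#: The closed set of composite kinds.
CompositionKind = ("serial", "hierarchical", "conditional")


@dataclass(frozen=True)
class ModelReference:
    """Pointer to a deployed model plus how to shape its input.

    ``input_mapping`` maps upstream output fields to downstream input fields;
    ``None`` means identity (the whole upstream record is passed through).
    """

    endpoint_key: str
    input_mapping: tuple[tuple[str, str], ...] | None = None

    def __post_init__(self) -> None:
        if not self.endpoint_key.startswith("/"):
            raise ValueError(f"endpoint key {self.endpoint_key!r} must start with '/'")
        if self.input_mapping is not None and not isinstance(self.input_mapping, tuple):
            object.__setattr__(self, "input_mapping", tuple(dict(self.input_mapping).items()))


def _short_version(version: str) -> str:
    parts = version.split(".")
    return ".".join(parts[:2])


def make_executive_package(
    source: str,
    ko_id: PersistentId,
    title: str,
    base_url: str | None = None,
    endpoint_path: str = "/run",
    function_name: str = "run",
    description: str = "",
) -> KnowledgeObjectPackage:
    """Wrap generated executive source into a standard KO package."""
    service_version = _short_version(ko_id.version)
    if base_url is None:
        base_url = f"/ipp/{ko_id.name}/{service_version}"
    entry = "executive.py"
    return KnowledgeObjectPackage(
        metadata=KoMetadata(
            id=ko_id,
            title=title,
            contributors=("kocompose composition generator",),
            ko_version=ko_id.version,
            description=description,
        ),
        deployment=DeploymentSpec(
            endpoint_path=endpoint_path,
            engine="python",
            entry=entry,
            artifacts=(entry,),
            function_name=function_name,
        ),
        service=ServiceSpec(
            service_version=service_version,
            title=title,
            base_url=base_url,
            paths=(endpoint_path,),
            description=description,
        ),
        payload={entry: source.encode("utf-8")},
    )


_SERIAL_TEMPLATE = '''\
"""Serial executive: engages each referenced model in order, piping outputs."""

REFS = {refs!r}


def run(inputs):
    record = inputs
    for key, mapping in REFS:
        if mapping is None:
            payload = record
        else:
            payload = {{dst: record[src] for src, dst in mapping}}
        record = ko_context(key, payload)
    return record
'''

_CONDITIONAL_TEMPLATE = '''\
"""Conditional executive: exactly one branch model is engaged per request."""

PREDICATE_FIELD = {predicate_field!r}
BRANCHES = {branches!r}
DEFAULT = {default!r}


def run(inputs):
    value = inputs[PREDICATE_FIELD]
    branch = BRANCHES.get(value, DEFAULT)
    if branch is None:
        raise ValueError(
            "no branch mapped for %s=%r and no default branch" % (PREDICATE_FIELD, value)
        )
    key, mapping = branch
    if mapping is None:
        payload = inputs
    else:
        payload = {{dst: inputs[src] for src, dst in mapping}}
    return ko_context(key, payload)
'''


def make_serial_executive(
    refs: Sequence[ModelReference],
    ko_id: PersistentId,
    title: str = "Serial executive",
    base_url: str | None = None,
    endpoint_path: str = "/run",
) -> KnowledgeObjectPackage:
    """Generate a KO whose payload calls each reference in order.

    Each model's output is shaped through the next reference's input mapping
    (identity when omitted) and fed forward. With a single reference the
    executive is equivalent to the referenced model itself.
    """
    refs = list(refs)
    if not refs:
        raise ValueError("a serial executive needs at least one model reference")
    ref_rows = [(r.endpoint_key, r.input_mapping) for r in refs]
    source = _SERIAL_TEMPLATE.format(refs=ref_rows)
    return make_executive_package(
        source,
        ko_id,
        title,
        base_url=base_url,
        endpoint_path=endpoint_path,
        description="serial composite of: " + ", ".join(r.endpoint_key for r in refs),
    )


def make_conditional_executive(
    predicate_field: str,
    branch_map: Mapping[Any, ModelReference],
    ko_id: PersistentId,
    default: ModelReference | None = None,
    title: str = "Conditional executive",
    base_url: str | None = None,
    endpoint_path: str = "/run",
) -> KnowledgeObjectPackage:
    """Generate a KO dispatching to exactly one branch per request.

    The predicate field's value selects the branch; an unmapped value falls
    back to ``default`` or, when no default is given, raises inside the model
    (surfacing as a ``model_error`` at the gateway).
    """
    if not branch_map:
        raise ValueError("branch_map must be nonempty")
    branches = {
        value: (ref.endpoint_key, ref.input_mapping) for value, ref in branch_map.items()
    }
    default_row = None if default is None else (default.endpoint_key, default.input_mapping)
    source = _CONDITIONAL_TEMPLATE.format(
        predicate_field=predicate_field, branches=branches, default=default_row
    )
    return make_executive_package(
        source,
        ko_id,
        title,
        base_url=base_url,
        endpoint_path=endpoint_path,
        description="conditional composite on field " + predicate_field,
    )


def oracle_compose(functions: Iterable[Callable[[Any], Any]], value: Any) -> Any:
    """Plain nested function application, no gateway. Test oracle only.

    The empty chain is the identity.
    """
    for fn in functions:
        value = fn(value)
    return value
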
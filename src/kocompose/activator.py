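"""Activation and the API gateway.

The :class:`Activator` deploys packaged functions into a runtime through a
:class:`RuntimeAdapter`, records each deployment in its :class:`RuntimeContext`
(a live registry keyed by endpoint), and then acts as the gateway: it routes
external requests to deployed functions and resolves model-to-model references
so any deployed model can call any other without knowing its implementation.

One adapter ships: :class:`PythonAdapter`, which executes payload source in an
isolated in-process namespace. Other runtimes are reachable by implementing
the same adapter contract. The model-to-model facility is *injected* into the
payload namespace under the well-known name ``ko_context`` at invocation time,
so payload code stays engine-agnostic.
"""

from __future__ import annotations

import logging
import time
import uuid
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Mapping

from kocompose.ko_package import (
    DEFAULT_ENGINE_ALLOW_LIST,
    KnowledgeObjectPackage,
    PackageValidationError,
    load_package,
    validate_package,
)

__all__ = [
    "Activator",
    "ActivationError",
    "AdapterDeployError",
    "CompositionDepthError",
    "ContextEntry",
    "DeployedHandle",
    "DuplicateEndpointError",
    "GatewayResponse",
    "ModelInvocationError",
    "ModelResolutionError",
    "PythonAdapter",
    "RuntimeAdapter",
    "RuntimeContext",
    "CONTEXT_FACILITY_NAME",
    "DEFAULT_MAX_CALL_DEPTH",
]

logger = logging.getLogger(__name__)

#: Name under which the model-to-model call facility appears to payload code.
CONTEXT_FACILITY_NAME = "ko_context"

#: Depth guard breaking circular compositions.
DEFAULT_MAX_CALL_DEPTH = 32


class ActivationError(Exception):
    """Activation failed (unknown engine, invalid package, deploy error)."""


class DuplicateEndpointError(ActivationError):
    """Endpoint key already active and replace was not requested."""


class AdapterDeployError(Exception):
    """The runtime adapter could not instantiate the payload."""


class ModelResolutionError(Exception):
    """A model-to-model reference named no active deployment."""


class CompositionDepthError(Exception):
    """Model-to-model call chain exceeded the configured depth (cycle guard)."""


class ModelInvocationError(Exception):
    """A deployed model raised during invocation; carries the model's message."""

    def __init__(self, endpoint_key: str, cause: BaseException):
        super().__init__(f"model at {endpoint_key} failed: {cause}")
        self.endpoint_key = endpoint_key
        self.cause = cause


@dataclass(frozen=True)
class DeployedHandle:
    """Opaque reference to a function instantiated inside a runtime."""

    token: str
    engine_name: str


class RuntimeAdapter:
    """Contract between the activator and a runtime engine.

    Implementations deploy payload artifacts, invoke the instantiated function
    with a one-record input plus the injected context facility, and undeploy.
    Payloads are assumed to be pure, stateless functions.
    """

    engine_name: str = ""

    def deploy(
        self, artifacts: Mapping[str, bytes], entry: str, function_name: str
    ) -> DeployedHandle:
        raise NotImplementedError

    def invoke(
        self, handle: DeployedHandle, payload: Any, context: Callable[[str, Any], Any]
    ) -> Any:
        raise NotImplementedError

    def undeploy(self, handle: DeployedHandle) -> None:
        raise NotImplementedError


class PythonAdapter(RuntimeAdapter):
    """Executes payload source files in an isolated in-process namespace."""

    engine_name = "python"

    def __init__(self) -> None:
        self._deployments: dict[str, tuple[dict, Callable]] = {}

    def deploy(
        self, artifacts: Mapping[str, bytes], entry: str, function_name: str
    ) -> DeployedHandle:
        namespace: dict[str, Any] = {"__builtins__": __builtins__}
        try:
            for name, source in artifacts.items():
                if name != entry:
                    exec(compile(source, name, "exec"), namespace)
            exec(compile(artifacts[entry], entry, "exec"), namespace)
        except KeyError as exc:
            raise AdapterDeployError(f"entry artifact {entry!r} missing: {exc}") from exc
        except Exception as exc:
            raise AdapterDeployError(f"payload failed to load: {exc}") from exc
        fn = namespace.get(function_name)
        if not callable(fn):
            raise AdapterDeployError(
                f"entry {entry!r} does not define a callable {function_name!r}"
            )
        token = uuid.uuid4().hex
        self._deployments[token] = (namespace, fn)
        return DeployedHandle(token=token, engine_name=self.engine_name)

    def invoke(
        self, handle: DeployedHandle, payload: Any, context: Callable[[str, Any], Any]
    ) -> Any:
        namespace, fn = self._deployments[handle.token]
        namespace[CONTEXT_FACILITY_NAME] = context
        try:
            return fn(payload)
        finally:
            namespace.pop(CONTEXT_FACILITY_NAME, None)

    def undeploy(self, handle: DeployedHandle) -> None:
        self._deployments.pop(handle.token, None)


@dataclass
class ContextEntry:
    endpoint_key: str
    puid: str
    handle: DeployedHandle | None
    status: str  # "active" | "failed"
    activated_at: float
    http_method: str = "post"
    error: str = ""

    def summary(self) -> dict:
        return {
            "endpoint": self.endpoint_key,
            "ko": self.puid,
            "status": self.status,
            "engine": self.handle.engine_name if self.handle else "",
            "activated_at": self.activated_at,
        }


@dataclass
class RuntimeContext:
    """The activator's dynamic registry of deployed models.

    ``entries`` holds only active deployments, keyed by endpoint; it is
    refreshed on every activate/deactivate. Failed activations are retained
    separately for inspection and never affect routing.
    """

    entries: dict[str, ContextEntry] = field(default_factory=dict)
    failures: list[ContextEntry] = field(default_factory=list)

    def active_keys(self) -> list[str]:
        return list(self.entries)


@dataclass
class GatewayResponse:
    status: str  # ok | not_found | method_not_allowed | model_error | bad_input
    body: dict
    model_ref: str = ""


class Activator:
    """Deploys KOs via adapters, keeps the runtime context, routes requests."""

    def __init__(
        self,
        adapters: list[RuntimeAdapter] | None = None,
        max_call_depth: int = DEFAULT_MAX_CALL_DEPTH,
        engine_allow_list: tuple[str, ...] = DEFAULT_ENGINE_ALLOW_LIST,
    ) -> None:
        if max_call_depth < 1:
            raise ValueError("max_call_depth must be >= 1")
        self.max_call_depth = max_call_depth
        self.engine_allow_list = tuple(engine_allow_list)
        self.context = RuntimeContext()
        self._adapters: dict[str, RuntimeAdapter] = {}
        #: (endpoint_key, depth) per invocation; depth 1 = external route.
        self.call_log: list[tuple[str, int]] = []
        for adapter in adapters if adapters is not None else [PythonAdapter()]:
            self.register_adapter(adapter)

    # -- lifecycle ----------------------------------------------------------

    def register_adapter(self, adapter: RuntimeAdapter) -> None:
        self._adapters[adapter.engine_name] = adapter

    def activate(
        self, pkg: KnowledgeObjectPackage, replace: bool = False
    ) -> ContextEntry:
        """Deploy a package and register it; atomic (context untouched on failure).

        An unknown engine yields a ``failed`` entry (recorded, not raised) so
        one bad KO never blocks the rest of a shelf. A duplicate endpoint key
        raises unless ``replace`` is set.
        """
        report = validate_package(pkg, self.engine_allow_list)
        if not report.ok:
            raise PackageValidationError(
                f"package {pkg.metadata.id} failed validation", report
            )
        key = pkg.endpoint_key
        adapter = self._adapters.get(pkg.deployment.engine)
        started = time.monotonic()
        if adapter is None:
            entry = ContextEntry(
                endpoint_key=key,
                puid=str(pkg.metadata.id),
                handle=None,
                status="failed",
                activated_at=time.time(),
                error=f"no adapter registered for engine {pkg.deployment.engine!r}",
            )
            self.context.failures.append(entry)
            logger.warning("activation failed for %s: %s", key, entry.error)
            return entry
        if key in self.context.entries:
            if not replace:
                raise DuplicateEndpointError(
                    f"endpoint {key} already active; pass replace=True to supersede"
                )
            self.deactivate(key)
        try:
            handle = adapter.deploy(
                pkg.payload, pkg.deployment.entry, pkg.deployment.function_name
            )
        except AdapterDeployError as exc:
            entry = ContextEntry(
                endpoint_key=key,
                puid=str(pkg.metadata.id),
                handle=None,
                status="failed",
                activated_at=time.time(),
                error=str(exc),
            )
            self.context.failures.append(entry)
            logger.warning("activation failed for %s: %s", key, exc)
            return entry
        entry = ContextEntry(
            endpoint_key=key,
            puid=str(pkg.metadata.id),
            handle=handle,
            status="active",
            activated_at=time.time(),
            http_method=pkg.deployment.http_method,
        )
        self.context.entries[key] = entry
        logger.info(
            "activated %s at %s in %.1f ms",
            entry.puid,
            key,
            (time.monotonic() - started) * 1e3,
        )
        return entry

    def activate_shelf(self, shelf_dir: str | Path, replace: bool = False) -> list[ContextEntry]:
        """Activate every KO package directory (or zip) found under ``shelf_dir``."""
        shelf_dir = Path(shelf_dir)
        entries = []
        for item in sorted(shelf_dir.iterdir()):
            if item.name.startswith(".") or item.suffix == ".json":
                continue  # manifests etc.
            if item.is_dir() or item.suffix == ".zip":
                entries.append(self.activate(load_package(item), replace=replace))
        return entries

    def deactivate(self, endpoint_key: str) -> ContextEntry | None:
        """Undeploy and drop an entry; unknown keys are a logged no-op."""
        entry = self.context.entries.pop(endpoint_key, None)
        if entry is None:
            logger.warning("deactivate: %s is not active", endpoint_key)
            return None
        if entry.handle is not None:
            self._adapters[entry.handle.engine_name].undeploy(entry.handle)
        logger.info("deactivated %s", endpoint_key)
        return entry

    def deactivate_all(self) -> None:
        for key in list(self.context.entries):
            self.deactivate(key)

    # -- gateway ------------------------------------------------------------

    def route(self, path: str, method: str, payload: Any) -> GatewayResponse:
        """Route an external request to the deployed model at ``path``.

        Model exceptions surface as ``model_error`` responses carrying the
        model's endpoint key; the gateway itself never crashes on them.
        """
        entry = self.context.entries.get(path)
        if entry is None:
            return GatewayResponse("not_found", {"error": f"no active model at {path}"})
        if method.lower() != entry.http_method:
            return GatewayResponse(
                "method_not_allowed",
                {"error": f"{path} accepts {entry.http_method.upper()} only"},
                model_ref=path,
            )
        if not isinstance(payload, Mapping):
            return GatewayResponse(
                "bad_input",
                {"error": "request body must be a JSON object"},
                model_ref=path,
            )
        try:
            result = self._invoke(entry, payload, depth=1)
        except (ModelInvocationError, ModelResolutionError, CompositionDepthError) as exc:
            logger.info("route %s -> model_error: %s", path, exc)
            return GatewayResponse("model_error", {"error": str(exc)}, model_ref=path)
        logger.info("route %s -> ok", path)
        return GatewayResponse(
            "ok",
            {"result": result, "info": {"ko": entry.puid, "endpoint": path}},
            model_ref=path,
        )

    def resolve_and_call(self, ref: str, payload: Any, depth: int = 1) -> Any:
        """Resolve a model reference and invoke it (model-to-model path).

        Returns exactly what an external route of the same reference would
        return in its ``result`` field.
        """
        if depth >= self.max_call_depth:
            raise CompositionDepthError(
                f"call depth {depth} reached max_call_depth={self.max_call_depth} "
                f"while resolving {ref}; circular composition?"
            )
        entry = self.context.entries.get(ref)
        if entry is None:
            raise ModelResolutionError(f"no active model for reference {ref}")
        return self._invoke(entry, payload, depth=depth + 1)

    def _invoke(self, entry: ContextEntry, payload: Any, depth: int) -> Any:
        adapter = self._adapters[entry.handle.engine_name]
        facility = self._make_facility(depth)
        self.call_log.append((entry.endpoint_key, depth))
        try:
            return adapter.invoke(entry.handle, payload, facility)
        except (ModelResolutionError, CompositionDepthError, ModelInvocationError):
            raise
        except Exception as exc:
            raise ModelInvocationError(entry.endpoint_key, exc) from exc

    def _make_facility(self, depth: int) -> Callable[[str, Any], Any]:
        def call(ref: str, payload: Any) -> Any:
            return self.resolve_and_call(ref, payload, depth=depth)

        return call

    # -- introspection ------------------------------------------------------

    def invocation_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for key, _ in self.call_log:
            counts[key] = counts.get(key, 0) + 1
        return counts

    def context_summaries(self) -> list[dict]:
        return [entry.summary() for entry in self.context.entries.values()]
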
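"""Knowledge Object packages: the format layer.

A KO package is a directory (or zip archive) holding three descriptor files
plus the executable payload:

* ``metadata.json`` — title, contributors, KO version, and the persistent
  unique identifier (PUID), rendered ``naan/name/version``.
* ``deployment.yaml`` — how to instantiate the payload: runtime engine, entry
  artifact, artifact list, and the name of the instantiable function, keyed
  by the single endpoint path and HTTP method.
* ``service.yaml`` — an OpenAPI 3.0 service description whose first server
  entry carries the partial base URL (e.g. ``/ipp/bmicalculator/1.0``) and
  whose paths declare the endpoint.

Payload source files sit beside the descriptors. Loading is permissive
(cross-file consistency is NOT enforced at load time); :func:`validate_package`
performs all consistency checks and returns findings instead of raising.
"""

from __future__ import annotations

import json
import re
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "PersistentId",
    "KoMetadata",
    "DeploymentSpec",
    "ServiceSpec",
    "KnowledgeObjectPackage",
    "Finding",
    "ValidationReport",
    "KoError",
    "DeploymentParseError",
    "ServiceParseError",
    "PackageLoadError",
    "PackageValidationError",
    "parse_deployment_description",
    "emit_deployment_description",
    "parse_service_description",
    "emit_service_description",
    "load_package",
    "write_package",
    "validate_package",
    "DESCRIPTOR_FILES",
    "DEFAULT_ENGINE_ALLOW_LIST",
]

DESCRIPTOR_FILES = ("metadata.json", "deployment.yaml", "service.yaml")

#: Engines for which validation raises no warning. Only ``python`` has a
#: shipped adapter; the others are recognized runtime tokens.
DEFAULT_ENGINE_ALLOW_LIST = ("python", "node", "R")

_VERSION_RE = re.compile(r"^\d+\.\d+(\.\d+)?$")


class KoError(Exception):
    """Base error for the KO format layer."""


class DeploymentParseError(KoError):
    """Deployment description is malformed or missing required fields."""


class ServiceParseError(KoError):
    """Service description is malformed or missing required blocks."""


class PackageLoadError(KoError):
    """A package on disk is missing files or structurally broken."""


class PackageValidationError(KoError):
    """A package failed validation; the report rides along."""

    def __init__(self, message: str, report: "ValidationReport"):
        super().__init__(message)
        self.report = report


@dataclass(frozen=True)
class PersistentId:
    """Persistent unique identifier (PUID) in ark-like ``naan/name/version`` form."""

    naan: str
    name: str
    version: str

    def __post_init__(self) -> None:
        for part, label in ((self.naan, "naan"), (self.name, "name"), (self.version, "version")):
            if not part:
                raise ValueError(f"PersistentId {label} must be nonempty")
        if not _VERSION_RE.match(self.version):
            raise ValueError(
                f"PersistentId version {self.version!r} must match MAJOR.MINOR[.PATCH]"
            )

    def __str__(self) -> str:
        return f"{self.naan}/{self.name}/{self.version}"

    @classmethod
    def from_string(cls, text: str) -> "PersistentId":
        parts = text.split("/")
        if len(parts) != 3:
            raise ValueError(f"PUID {text!r} is not of the form naan/name/version")
        return cls(*parts)


@dataclass(frozen=True)
class KoMetadata:
    id: PersistentId
    title: str
    contributors: tuple[str, ...] = ()
    ko_version: str = "1.0"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.title:
            raise ValueError("KO title must be nonempty")
        object.__setattr__(self, "contributors", tuple(self.contributors))


@dataclass(frozen=True)
class DeploymentSpec:
    """How to instantiate a packaged function (one endpoint, POST only)."""

    endpoint_path: str
    engine: str
    entry: str
    artifacts: tuple[str, ...]
    function_name: str
    http_method: str = "post"

    def __post_init__(self) -> None:
        object.__setattr__(self, "artifacts", tuple(self.artifacts))
        if not self.endpoint_path.startswith("/"):
            raise ValueError(f"endpoint path {self.endpoint_path!r} must start with '/'")
        if self.entry not in self.artifacts:
            raise ValueError(f"entry {self.entry!r} must appear among artifacts")
        if not self.engine:
            raise ValueError("engine must be nonempty")


@dataclass(frozen=True)
class ServiceSpec:
    """The slice of an OpenAPI 3.0 service description this stack consumes."""

    service_version: str
    title: str
    base_url: str
    paths: tuple[str, ...]
    api_format_version: str = "3.0.0"
    license_name: str = ""
    contact: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "paths", tuple(self.paths))
        if not self.paths:
            raise ValueError("service description must declare at least one path")


@dataclass
class KnowledgeObjectPackage:
    metadata: KoMetadata
    deployment: DeploymentSpec
    service: ServiceSpec
    payload: dict[str, bytes] = field(default_factory=dict)

    @property
    def endpoint_key(self) -> str:
        """Routable key: service base URL joined with the deployment path."""
        return self.service.base_url + self.deployment.endpoint_path


@dataclass(frozen=True)
class Finding:
    severity: str  # "error" | "warning"
    code: str
    message: str
    component: str


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(f.severity == "error" for f in self.findings)

    def add(self, severity: str, code: str, message: str, component: str) -> None:
        self.findings.append(Finding(severity, code, message, component))

    def to_json(self) -> str:
        return json.dumps(
            {
                "ok": self.ok,
                "findings": [
                    {
                        "severity": f.severity,
                        "code": f.code,
                        "message": f.message,
                        "component": f.component,
                    }
                    for f in self.findings
                ],
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# Deployment descriptions (Box-3 dialect)
# ---------------------------------------------------------------------------

def parse_deployment_description(text: str) -> DeploymentSpec:
    """Parse a deployment description.

    The document has one top-level endpoint-path key mapping to one HTTP
    method (``post``) mapping to ``engine``/``entry``/``artifact``/``function``.
    A scalar ``artifact`` value is normalized to a one-element list; a missing
    ``artifact`` defaults to the entry file.
    """
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise DeploymentParseError(f"malformed YAML{where}: {exc}") from exc
    if not isinstance(doc, Mapping) or not doc:
        raise DeploymentParseError("deployment description must map one endpoint path")
    if len(doc) != 1:
        raise DeploymentParseError(
            f"one endpoint per KO: found {len(doc)} top-level paths {sorted(doc)}"
        )
    (path, methods), = doc.items()
    if not isinstance(methods, Mapping) or not methods:
        raise DeploymentParseError(f"path {path!r} must map an HTTP method block")
    if len(methods) != 1:
        raise DeploymentParseError(f"path {path!r} declares multiple methods {sorted(methods)}")
    (method, body), = methods.items()
    method = str(method).lower()
    if method != "post":
        raise DeploymentParseError(f"only 'post' deployments are supported, got {method!r}")
    if not isinstance(body, Mapping):
        raise DeploymentParseError(f"method block for {path!r} must be a mapping")
    missing = [key for key in ("engine", "entry", "function") if not body.get(key)]
    if missing:
        raise DeploymentParseError(
            "deployment description missing required field(s): " + ", ".join(missing)
        )
    artifact = body.get("artifact", body["entry"])
    if isinstance(artifact, str):
        artifacts: tuple[str, ...] = (artifact,)
    elif isinstance(artifact, Iterable):
        artifacts = tuple(str(a) for a in artifact)
    else:
        raise DeploymentParseError(f"artifact must be a filename or list, got {artifact!r}")
    return DeploymentSpec(
        endpoint_path=str(path),
        http_method=method,
        engine=str(body["engine"]),
        entry=str(body["entry"]),
        artifacts=artifacts,
        function_name=str(body["function"]),
    )


def emit_deployment_description(spec: DeploymentSpec) -> str:
    doc = {
        spec.endpoint_path: {
            spec.http_method: {
                "engine": spec.engine,
                "entry": spec.entry,
                "artifact": list(spec.artifacts),
                "function": spec.function_name,
            }
        }
    }
    return yaml.safe_dump(doc, sort_keys=False)


# ---------------------------------------------------------------------------
# Service descriptions (OpenAPI 3.0, Box-4 dialect)
# ---------------------------------------------------------------------------

def parse_service_description(text: str) -> ServiceSpec:
    """Parse the OpenAPI 3.0 fields the activator consumes.

    The base URL is taken from the first ``servers`` entry; the service
    version from ``info.version``; paths are collected in document order.
    """
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ServiceParseError(f"malformed YAML: {exc}") from exc
    if not isinstance(doc, Mapping):
        raise ServiceParseError("service description must be a mapping")
    info = doc.get("info")
    if not isinstance(info, Mapping) or "version" not in info:
        raise ServiceParseError("service description missing info.version")
    servers = doc.get("servers")
    if not isinstance(servers, list) or not servers:
        raise ServiceParseError("service description missing servers block")
    first = servers[0]
    base_url = first.get("url") if isinstance(first, Mapping) else None
    if not base_url:
        raise ServiceParseError("first server entry has no url")
    paths = doc.get("paths")
    if not isinstance(paths, Mapping) or not paths:
        raise ServiceParseError("service description declares no paths")
    license_name = ""
    lic = info.get("license")
    if isinstance(lic, Mapping):
        license_name = str(lic.get("name", ""))
    contact = ""
    con = info.get("contact")
    if isinstance(con, Mapping):
        contact = str(con.get("name") or con.get("email") or "")
    return ServiceSpec(
        api_format_version=str(doc.get("openapi", "3.0.0")),
        service_version=str(info["version"]),
        title=str(info.get("title", "")),
        description=str(info.get("description", "")),
        base_url=str(base_url),
        paths=tuple(str(p) for p in paths),
        license_name=license_name,
        contact=contact,
    )


def emit_service_description(spec: ServiceSpec) -> str:
    info: dict = {
        "version": spec.service_version,
        "title": spec.title,
        "description": spec.description,
    }
    if spec.license_name:
        info["license"] = {"name": spec.license_name}
    if spec.contact:
        info["contact"] = {"name": spec.contact}
    doc = {
        "openapi": spec.api_format_version,
        "info": info,
        "servers": [{"url": spec.base_url}],
        "paths": {
            p: {"post": {"responses": {"200": {"description": "model output"}}}}
            for p in spec.paths
        },
    }
    return yaml.safe_dump(doc, sort_keys=False)


# ---------------------------------------------------------------------------
# Package load / write / validate
# ---------------------------------------------------------------------------

def _metadata_to_json(meta: KoMetadata) -> str:
    return json.dumps(
        {
            "id": str(meta.id),
            "title": meta.title,
            "contributors": list(meta.contributors),
            "ko_version": meta.ko_version,
            "description": meta.description,
        },
        indent=2,
    )


def _metadata_from_json(text: str) -> KoMetadata:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise PackageLoadError(f"metadata.json is not valid JSON: {exc}") from exc
    try:
        puid = PersistentId.from_string(doc["id"])
    except (KeyError, ValueError) as exc:
        raise PackageLoadError(f"metadata.json has a bad or missing PUID: {exc}") from exc
    return KoMetadata(
        id=puid,
        title=doc.get("title", ""),
        contributors=tuple(doc.get("contributors", ())),
        ko_version=str(doc.get("ko_version", "1.0")),
        description=doc.get("description", ""),
    )


def _read_tree(location: Path) -> dict[str, bytes]:
    """Read all files under a package location (directory or zip) into memory."""
    files: dict[str, bytes] = {}
    if location.is_dir():
        for path in sorted(location.rglob("*")):
            if path.is_file():
                files[path.relative_to(location).as_posix()] = path.read_bytes()
    elif zipfile.is_zipfile(location):
        with zipfile.ZipFile(location) as zf:
            for name in zf.namelist():
                if name.endswith("/"):
                    continue
                if name in files:
                    raise PackageLoadError(f"duplicate payload filename in archive: {name}")
                files[name] = zf.read(name)
    else:
        raise PackageLoadError(f"{location} is neither a directory nor a zip archive")
    return files


def load_package(location: str | Path) -> KnowledgeObjectPackage:
    """Load a KO package from a directory or zip archive.

    Payload bytes are loaded verbatim. Cross-file invariants are *not*
    enforced here; run :func:`validate_package` for that.
    """
    location = Path(location)
    if not location.exists():
        raise PackageLoadError(f"package location {location} does not exist")
    files = _read_tree(location)
    missing = [name for name in DESCRIPTOR_FILES if name not in files]
    if missing:
        raise PackageLoadError(
            f"package at {location} missing required file(s): " + ", ".join(missing)
        )
    metadata = _metadata_from_json(files["metadata.json"].decode("utf-8"))
    deployment = parse_deployment_description(files["deployment.yaml"].decode("utf-8"))
    service = parse_service_description(files["service.yaml"].decode("utf-8"))
    payload = {name: data for name, data in files.items() if name not in DESCRIPTOR_FILES}
    return KnowledgeObjectPackage(metadata, deployment, service, payload)


def validate_package(
    pkg: KnowledgeObjectPackage,
    engine_allow_list: Iterable[str] = DEFAULT_ENGINE_ALLOW_LIST,
) -> ValidationReport:
    """Check cross-component consistency; findings are returned, never raised."""
    report = ValidationReport()
    for name in pkg.deployment.artifacts:
        if name not in pkg.payload:
            code = "ENTRY_MISSING" if name == pkg.deployment.entry else "ARTIFACT_MISSING"
            report.add("error", code, f"artifact {name!r} absent from payload", "payload")
    if pkg.deployment.endpoint_path not in pkg.service.paths:
        report.add(
            "error",
            "PATH_MISMATCH",
            f"deployment path {pkg.deployment.endpoint_path!r} not among service paths "
            f"{list(pkg.service.paths)}",
            "service",
        )
    if not _VERSION_RE.match(pkg.metadata.id.version):
        report.add(
            "error",
            "PUID_MALFORMED",
            f"PUID version {pkg.metadata.id.version!r} not MAJOR.MINOR[.PATCH]",
            "metadata",
        )
    if not _VERSION_RE.match(pkg.service.service_version):
        report.add(
            "error",
            "VERSION_MALFORMED",
            f"service version {pkg.service.service_version!r} not MAJOR.MINOR[.PATCH]",
            "service",
        )
    base = pkg.service.base_url.rstrip("/")
    if not base.endswith("/" + pkg.service.service_version):
        report.add(
            "error",
            "BASE_URL_VERSION",
            f"base url {pkg.service.base_url!r} does not end with the service version "
            f"segment /{pkg.service.service_version}",
            "service",
        )
    if pkg.deployment.engine not in tuple(engine_allow_list):
        report.add(
            "warning",
            "ENGINE_UNKNOWN",
            f"engine {pkg.deployment.engine!r} not in allow-list",
            "deployment",
        )
    return report


def write_package(
    pkg: KnowledgeObjectPackage,
    location: str | Path,
    engine_allow_list: Iterable[str] = DEFAULT_ENGINE_ALLOW_LIST,
) -> Path:
    """Write a validated package to a directory, or to a zip if the path ends ``.zip``.

    Refuses invalid packages; the :class:`ValidationReport` is attached to the
    raised :class:`PackageValidationError`.
    """
    report = validate_package(pkg, engine_allow_list)
    if not report.ok:
        raise PackageValidationError(
            f"refusing to write invalid package {pkg.metadata.id}", report
        )
    location = Path(location)
    files: dict[str, bytes] = {
        "metadata.json": _metadata_to_json(pkg.metadata).encode("utf-8"),
        "deployment.yaml": emit_deployment_description(pkg.deployment).encode("utf-8"),
        "service.yaml": emit_service_description(pkg.service).encode("utf-8"),
    }
    files.update(pkg.payload)
    if location.suffix == ".zip":
        location.parent.mkdir(parents=True, exist_ok=True)
        with zipfile.ZipFile(location, "w", zipfile.ZIP_DEFLATED) as zf:
            for name, data in files.items():
                # fixed timestamp keeps archives byte-reproducible
                info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
                zf.writestr(info, data)
    else:
        location.mkdir(parents=True, exist_ok=True)
        for name, data in files.items():
            target = location / name
            target.parent.mkdir(parents=True, exist_ok=True)
            target.write_bytes(data)
    return location
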
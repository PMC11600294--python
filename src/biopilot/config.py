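"""Run configuration and workspace plumbing.

A run is driven by a small YAML document carrying the three user inputs —
an ordered list of ``path: description`` data entries, a free-text final
objective, and an optional blacklist of prohibited software — plus a
backend profile and run-level limits.  This module parses and validates
that document into an :class:`AnalysisConfig` and materializes the run
workspace (scripts / output / logs directories) on disk.
"""

from __future__ import annotations

import dataclasses
import os
import time
import uuid
from pathlib import Path
from typing import Any

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

__all__ = [
    "ConfigError",
    "ConfigParseError",
    "ConfigValidationError",
    "WorkspaceError",
    "DataEntry",
    "AnalysisConfig",
    "Workspace",
    "parse_config",
    "parse_config_file",
    "serialize_config",
    "init_workspace",
]


class ConfigError(ValueError):
    """Base class for configuration problems."""


class ConfigParseError(ConfigError):
    """The document is not syntactically valid YAML."""


class ConfigValidationError(ConfigError):
    """The document parsed but violates the configuration schema."""


class WorkspaceError(OSError):
    """Workspace initialization failed (unwritable location, run-id collision)."""


class DataEntry(BaseModel):
    """One ``path: description`` pair of the user's data list."""

    model_config = ConfigDict(frozen=True)

    path: str
    description: str

    @field_validator("path", "description")
    @classmethod
    def _non_empty(cls, v: str) -> str:
        if not v or not v.strip():
            raise ValueError("must be non-empty")
        if "\n" in v:
            raise ValueError("must be a single line")
        return v

    @field_validator("path")
    @classmethod
    def _no_delimiter(cls, v: str) -> str:
        # ": " is the rendering delimiter; allowing it in a path would make
        # the "path: description" rendering ambiguous.
        if ": " in v:
            raise ValueError("path may not contain the ': ' delimiter")
        return v

    def render(self) -> str:
        return f"{self.path}: {self.description}"


class AnalysisConfig(BaseModel):
    """The user's entire input plus run-level settings with defaults filled."""

    model_config = ConfigDict(frozen=True)

    data_entries: list[DataEntry] = Field(min_length=1)
    global_goal: str
    blacklist: list[str] = Field(default_factory=list)
    backend_profile: str = "transcript"
    output_dir: str = "./runs"
    max_repair_attempts: int = Field(default=5, ge=0)
    decoding_temperature: float = Field(default=0.0, ge=0.0)
    step_timeout: float = Field(default=3600.0, gt=0.0)

    @field_validator("global_goal")
    @classmethod
    def _goal_non_empty(cls, v: str) -> str:
        if not v or not v.strip():
            raise ValueError("must be non-empty")
        return v

    @field_validator("blacklist")
    @classmethod
    def _dedupe_casefold(cls, v: list[str]) -> list[str]:
        seen: set[str] = set()
        out: list[str] = []
        for name in v:
            key = name.casefold()
            if key not in seen:
                seen.add(key)
                out.append(name)
        return out

    @field_validator("data_entries")
    @classmethod
    def _unique_paths(cls, v: list[DataEntry]) -> list[DataEntry]:
        seen: set[str] = set()
        for e in v:
            if e.path in seen:
                raise ValueError(f"duplicate data path: {e.path!r}")
            seen.add(e.path)
        return v


@dataclasses.dataclass(frozen=True)
class Workspace:
    """The on-disk layout of one run: scripts, outputs and logs under a root."""

    root: Path
    scripts_dir: Path
    output_dir: Path
    logs_dir: Path
    run_id: str


_TOP_KEYS = {"data", "goal", "blacklist", "backend", "output_dir", "limits"}
_LIMIT_KEYS = {"max_repair_attempts", "temperature", "step_timeout"}


def _data_entries_from(node: Any) -> list[DataEntry]:
    """Accept either a mapping path->description or an ordered list of
    single-key mappings (the YAML idiom ``- ./a.fastq: reads``)."""
    pairs: list[tuple[Any, Any]] = []
    if isinstance(node, dict):
        pairs = list(node.items())
    elif isinstance(node, list):
        for item in node:
            if not isinstance(item, dict) or len(item) != 1:
                raise ConfigValidationError(
                    "each 'data' list item must be a single 'path: description' mapping"
                )
            pairs.append(next(iter(item.items())))
    else:
        raise ConfigValidationError("'data' must be a mapping or a list of mappings")
    if not pairs:
        raise ConfigValidationError("'data' must contain at least one entry")
    entries = []
    seen: set[str] = set()
    for path, desc in pairs:
        if not isinstance(path, str) or not isinstance(desc, str):
            raise ConfigValidationError("data paths and descriptions must be strings")
        if path in seen:
            raise ConfigValidationError(f"duplicate data path: {path!r}")
        seen.add(path)
        try:
            entries.append(DataEntry(path=path, description=desc))
        except ValueError as exc:
            raise ConfigValidationError(f"invalid data entry {path!r}: {exc}") from exc
    return entries


def parse_config(text: str, base_dir: str | os.PathLike | None = None) -> AnalysisConfig:
    """Parse a YAML run configuration into a validated :class:`AnalysisConfig`.

    Parameters
    ----------
    text:
        The configuration document.
    base_dir:
        Directory the document was read from; a relative ``output_dir`` is
        resolved against it.  Data paths are kept exactly as given.

    Raises
    ------
    ConfigParseError
        Malformed YAML (message includes line context when available).
    ConfigValidationError
        Unknown keys, missing required inputs, or invalid values.
    """
    try:
        doc = yaml.safe_load(text)
    except yaml.MarkedYAMLError as exc:
        mark = exc.problem_mark
        where = f" at line {mark.line + 1}, column {mark.column + 1}" if mark else ""
        raise ConfigParseError(f"malformed configuration document{where}: {exc.problem}") from exc
    except yaml.YAMLError as exc:  # pragma: no cover - unmarked parser errors
        raise ConfigParseError(f"malformed configuration document: {exc}") from exc

    if doc is None:
        raise ConfigValidationError("empty configuration: missing required fields 'data', 'goal'")
    if not isinstance(doc, dict):
        raise ConfigValidationError("configuration root must be a mapping")

    unknown = sorted(set(doc) - _TOP_KEYS)
    if unknown:
        raise ConfigValidationError(f"unknown configuration keys: {', '.join(unknown)}")

    missing = [k for k in ("data", "goal") if k not in doc]
    if missing:
        raise ConfigValidationError(f"missing required field(s): {', '.join(missing)}")

    entries = _data_entries_from(doc["data"])

    goal = doc["goal"]
    if not isinstance(goal, str) or not goal.strip():
        raise ConfigValidationError("'goal' must be a non-empty string")

    blacklist = doc.get("blacklist") or []
    if not isinstance(blacklist, list) or not all(isinstance(b, str) for b in blacklist):
        raise ConfigValidationError("'blacklist' must be a list of software names")

    limits = doc.get("limits") or {}
    if not isinstance(limits, dict):
        raise ConfigValidationError("'limits' must be a mapping")
    unknown_limits = sorted(set(limits) - _LIMIT_KEYS)
    if unknown_limits:
        raise ConfigValidationError(f"unknown limit keys: {', '.join(unknown_limits)}")

    output_dir = doc.get("output_dir", "./runs")
    if base_dir is not None and not os.path.isabs(output_dir):
        output_dir = str(Path(base_dir) / output_dir)

    kwargs: dict[str, Any] = {
        "data_entries": entries,
        "global_goal": goal,
        "blacklist": blacklist,
        "backend_profile": doc.get("backend", "transcript"),
        "output_dir": output_dir,
    }
    if "max_repair_attempts" in limits:
        kwargs["max_repair_attempts"] = limits["max_repair_attempts"]
    if "temperature" in limits:
        kwargs["decoding_temperature"] = limits["temperature"]
    if "step_timeout" in limits:
        kwargs["step_timeout"] = limits["step_timeout"]

    try:
        return AnalysisConfig(**kwargs)
    except ValueError as exc:
        raise ConfigValidationError(str(exc)) from exc


def parse_config_file(path: str | os.PathLike) -> AnalysisConfig:
    p = Path(path)
    return parse_config(p.read_text(), base_dir=p.parent)


def serialize_config(config: AnalysisConfig) -> str:
    """Render a config back to YAML such that ``parse_config`` round-trips it."""
    doc = {
        "data": [{e.path: e.description} for e in config.data_entries],
        "goal": config.global_goal,
        "blacklist": list(config.blacklist),
        "backend": config.backend_profile,
        "output_dir": config.output_dir,
        "limits": {
            "max_repair_attempts": config.max_repair_attempts,
            "temperature": config.decoding_temperature,
            "step_timeout": config.step_timeout,
        },
    }
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)


def _new_run_id() -> str:
    return f"run-{time.strftime('%Y%m%dT%H%M%S')}-{uuid.uuid4().hex[:6]}"


def init_workspace(
    config: AnalysisConfig,
    run_id: str | None = None,
    overwrite: bool = False,
) -> Workspace:
    """Create the run directory tree and persist the resolved configuration.

    The root is ``<output_dir>/<run_id>`` with ``scripts/``, ``output/`` and
    ``logs/`` beneath it; a YAML copy of the resolved config is written into
    ``logs/`` so the run is self-describing.  An existing root for the same
    run id is refused unless ``overwrite`` is set.
    """
    rid = run_id or _new_run_id()
    root = Path(config.output_dir) / rid
    if root.exists() and not overwrite:
        raise WorkspaceError(f"run workspace already exists: {root} (pass overwrite to reuse)")
    try:
        scripts = root / "scripts"
        output = root / "output"
        logs = root / "logs"
        for d in (root, scripts, output, logs):
            d.mkdir(parents=True, exist_ok=True)
        (logs / "config.yaml").write_text(serialize_config(config))
    except OSError as exc:
        raise WorkspaceError(f"cannot initialize workspace at {root}: {exc}") from exc
    return Workspace(root=root, scripts_dir=scripts, output_dir=output, logs_dir=logs, run_id=rid)
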
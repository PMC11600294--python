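"""Confined shell execution: screening, running, and error classification.

Generated shell code is never run blindly.  It is first screened line-wise
against a denylist of command patterns (privilege escalation, destructive
operations outside the workspace, piping downloads into a shell); a
rejection is surfaced as an :class:`ErrorFinding` so the repair loop
regenerates the code instead of aborting the run.  Accepted scripts run
under ``bash`` with ``set -e`` prepended, working directory pinned to the
workspace root, a private allow-listed environment, both streams captured
with tail-preserving truncation, and a hard timeout.

Error classification is exit-code-primary: a run is an error iff the exit
status is non-zero, it timed out, or a configured error pattern matches
either stream.  A zero exit with chatter on stderr is *not* an error —
many bioinformatics tools log progress there.
"""

from __future__ import annotations

import dataclasses
import json
import os
import re
import shutil
import subprocess
import time
from pathlib import Path
from typing import Sequence

__all__ = [
    "SandboxError",
    "SandboxPolicy",
    "ExecutionResult",
    "ErrorFinding",
    "ScreenDecision",
    "DEFAULT_ERROR_PATTERNS",
    "default_denylist",
    "screen_commands",
    "execute",
    "detect_error",
    "TIMEOUT_EXIT_CODE",
]

# GNU-timeout convention for a killed process.
TIMEOUT_EXIT_CODE = 124

DEFAULT_ERROR_PATTERNS: tuple[str, ...] = (
    "command not found",
    "No such file or directory",
    "Traceback",
    "Error:",
    "error:",
    "Segmentation fault",
    "Killed",
)

# Environment variables allowed through to executed scripts.
_ENV_ALLOWLIST = ("PATH", "LANG", "LC_ALL", "TZ", "TERM")


class SandboxError(RuntimeError):
    """Infrastructure failure (e.g. container required but unavailable),
    distinct from failure of the executed script."""


def default_denylist(workspace_root: str | os.PathLike | None = None) -> tuple[str, ...]:
    """The default command denylist as regex patterns.

    Destructive file operations are only flagged on absolute paths outside
    the workspace; relative paths stay inside by working-directory
    discipline.
    """
    if workspace_root is not None:
        ws = re.escape(str(Path(workspace_root)).lstrip("/"))
        outside = rf"/(?!{ws})"
    else:
        outside = r"/"
    return (
        r"\bsudo\b",
        r"(?:^|[;&|]\s*)su\b",
        r"\bshutdown\b",
        r"\breboot\b",
        r"\bmkfs(?:\.\w+)?\b",
        r"\bdd\b[^\n]*\bof=/dev/",
        rf"\brm\b[^\n]*\s{outside}",
        rf"\b(?:chmod|chown)\b[^\n]*\s{outside}",
        r"\b(?:curl|wget)\b[^\n]*\|\s*(?:ba|z|da)?sh\b",
    )


@dataclasses.dataclass(frozen=True)
class SandboxPolicy:
    denylist: tuple[str, ...] = dataclasses.field(default_factory=default_denylist)
    confine_to_workspace: bool = True
    container_mode: bool = False
    container_image: str = "ubuntu:22.04"
    timeout: float = 3600.0
    capture_limit: int = 1_048_576  # bytes per stream, tail-preserving
    error_patterns: tuple[str, ...] = DEFAULT_ERROR_PATTERNS

    def __post_init__(self) -> None:
        if self.timeout <= 0:
            raise ValueError("timeout must be positive")
        if self.capture_limit <= 0:
            raise ValueError("capture_limit must be positive")


@dataclasses.dataclass(frozen=True)
class ExecutionResult:
    exit_code: int
    stdout_capture: str
    stderr_capture: str
    duration: float
    timed_out: bool = False
    stdout_truncated: bool = False
    stderr_truncated: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExecutionResult":
        return cls(**d)


@dataclasses.dataclass(frozen=True)
class ErrorFinding:
    is_error: bool
    excerpt: str = ""
    reason: str | None = None  # nonzero_exit | timeout | denylisted_command | error_pattern

    def __post_init__(self) -> None:
        if not self.is_error and self.excerpt:
            raise ValueError("a non-error finding must carry an empty excerpt")


@dataclasses.dataclass(frozen=True)
class ScreenDecision:
    accepted: bool
    offenses: tuple[tuple[int, str, str], ...] = ()  # (1-based line no, line, pattern)

    def as_finding(self) -> ErrorFinding:
        if self.accepted:
            return ErrorFinding(is_error=False)
        lines = "\n".join(f"line {n}: {line}  [pattern: {pat}]" for n, line, pat in self.offenses)
        return ErrorFinding(
            is_error=True,
            excerpt="generated code was rejected by the command screen:\n" + lines,
            reason="denylisted_command",
        )


_HEREDOC_RE = re.compile(r"<<-?\s*(['\"]?)(\w+)\1")


def screen_commands(shell_text: str, policy: SandboxPolicy) -> ScreenDecision:
    """Match every script line against the denylist.

    Comment lines and here-document bodies are excluded from screening.
    Any match rejects the script, listing every offending line.
    """
    compiled = [(pat, re.compile(pat)) for pat in policy.denylist]
    offenses: list[tuple[int, str, str]] = []
    heredoc_end: str | None = None
    for lineno, line in enumerate(shell_text.split("\n"), start=1):
        if heredoc_end is not None:
            if line.strip() == heredoc_end:
                heredoc_end = None
            continue
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        for pat, rx in compiled:
            if rx.search(line):
                offenses.append((lineno, line, pat))
        m = _HEREDOC_RE.search(line)
        if m:
            heredoc_end = m.group(2)
    return ScreenDecision(accepted=not offenses, offenses=tuple(offenses))


def _truncate_tail(text: str, limit: int) -> tuple[str, bool]:
    if len(text.encode(errors="replace")) <= limit:
        return text, False
    # keep the tail: shell errors trail
    tail = text.encode(errors="replace")[-limit:].decode(errors="replace")
    return tail, True


def execute(
    code,
    workspace,
    policy: SandboxPolicy,
    env_extra: dict[str, str] | None = None,
    audit_log=None,
) -> ExecutionResult:
    """Run a screened :class:`~biopilot.codegen.CodeBlock` inside the workspace.

    The script is persisted as ``scripts/step<N>_attempt<K>.sh`` with
    ``set -e`` prepended, executed with cwd = workspace root and a private
    environment, and its result persisted as JSON beside the script before
    returning.  ``env_extra`` lets callers prepend fixture tool directories
    to PATH.  In container mode the script runs inside a container with only
    the workspace bind-mounted.
    """
    script_path = Path(workspace.scripts_dir) / f"step{code.step_index}_attempt{code.attempt}.sh"
    script_path.write_text("#!/usr/bin/env bash\nset -e\n" + code.shell_text.rstrip("\n") + "\n")

    env = {k: os.environ[k] for k in _ENV_ALLOWLIST if k in os.environ}
    env["HOME"] = str(workspace.root)
    env["TMPDIR"] = str(workspace.root)
    if env_extra:
        env.update(env_extra)

    if policy.container_mode:
        runtime = shutil.which("docker") or shutil.which("podman")
        if runtime is None:
            raise SandboxError("container_mode requested but no container runtime found")
        argv = [
            runtime, "run", "--rm",
            "-v", f"{workspace.root}:{workspace.root}",
            "-w", str(workspace.root),
            policy.container_image,
            "bash", str(script_path),
        ]
    else:
        argv = ["bash", str(script_path)]

    if audit_log is not None:
        audit_log.append("execute", script=str(script_path), step=code.step_index,
                         attempt=code.attempt)

    start = time.monotonic()
    timed_out = False
    try:
        proc = subprocess.run(
            argv,
            cwd=str(workspace.root),
            env=env,
            capture_output=True,
            text=True,
            timeout=policy.timeout,
        )
        exit_code, out, err = proc.returncode, proc.stdout, proc.stderr
    except subprocess.TimeoutExpired as exc:
        timed_out = True
        exit_code = TIMEOUT_EXIT_CODE

        def _dec(b):
            if b is None:
                return ""
            return b.decode(errors="replace") if isinstance(b, bytes) else b

        out, err = _dec(exc.stdout), _dec(exc.stderr)
    duration = time.monotonic() - start

    out, out_trunc = _truncate_tail(out, policy.capture_limit)
    err, err_trunc = _truncate_tail(err, policy.capture_limit)
    result = ExecutionResult(
        exit_code=exit_code,
        stdout_capture=out,
        stderr_capture=err,
        duration=duration,
        timed_out=timed_out,
        stdout_truncated=out_trunc,
        stderr_truncated=err_trunc,
    )
    # persist streams and result beside the script
    script_path.with_suffix(".out").write_text(out)
    script_path.with_suffix(".err").write_text(err)
    script_path.with_suffix(".result.json").write_text(json.dumps(result.to_dict(), indent=2))
    return result


_EXCERPT_CONTEXT = 200
_EXCERPT_TAIL = 4000


def detect_error(
    result: ExecutionResult, patterns: Sequence[str] = DEFAULT_ERROR_PATTERNS
) -> ErrorFinding:
    """Classify an execution result; pure function of (result, patterns).

    ``is_error`` = non-zero exit OR timeout OR any pattern matching either
    capture.  The excerpt is the matched region with context when a pattern
    matched, else the tail of stderr (falling back to stdout).
    """
    match_region = None
    for pat in patterns:
        for stream in (result.stderr_capture, result.stdout_capture):
            idx = stream.find(pat)
            if idx >= 0:
                lo = max(0, idx - _EXCERPT_CONTEXT)
                hi = min(len(stream), idx + len(pat) + _EXCERPT_CONTEXT)
                match_region = stream[lo:hi]
                break
        if match_region is not None:
            break

    if result.timed_out:
        reason = "timeout"
    elif result.exit_code != 0:
        reason = "nonzero_exit"
    elif match_region is not None:
        reason = "error_pattern"
    else:
        return ErrorFinding(is_error=False)

    if match_region is not None:
        excerpt = match_region
    else:
        excerpt = result.stderr_capture[-_EXCERPT_TAIL:] or result.stdout_capture[-_EXCERPT_TAIL:]
    if reason == "timeout" and not excerpt:
        excerpt = f"execution timed out after {result.duration:.1f}s"
    if not excerpt:
        excerpt = f"exit status {result.exit_code} with empty output streams"
    return ErrorFinding(is_error=True, excerpt=excerpt, reason=reason)
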
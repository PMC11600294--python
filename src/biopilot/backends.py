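"""Language-model backend contract and implementations.

The agent talks to any backend through a single ``complete`` call.  Three
implementations are provided:

* :class:`TranscriptBackend` — a deterministic test double that answers
  prompts from a prerecorded matcher → response table.  This is the backend
  the offline test suite runs against; replaying a transcript is a pure
  function of (transcript, prompt).
* :class:`OpenAIChatBackend` — a thin adapter for any OpenAI-compatible
  chat-completions HTTP endpoint (stdlib ``urllib``; requires network and an
  API key, never exercised by the test suite).
* :class:`LocalCommandBackend` — a generic adapter for a local instruct
  model exposed as a subprocess that reads the prompt on stdin and writes
  the completion to stdout (e.g. a llama.cpp wrapper script).

Transcript matching normalizes whitespace and substitutes declared
run-specific placeholders (workspace paths, run ids) so a recorded
transcript replays in any temporary directory.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
import os
import re
import subprocess
import time
import urllib.error
import urllib.request
from pathlib import Path
from typing import Callable, Sequence

__all__ = [
    "BackendError",
    "TranscriptError",
    "BackendRequest",
    "BackendResponse",
    "TranscriptEntry",
    "Backend",
    "TranscriptBackend",
    "OpenAIChatBackend",
    "LocalCommandBackend",
    "load_transcript",
    "dump_transcript",
    "prompt_key",
    "resolve_backend",
]


class BackendError(RuntimeError):
    """Configuration-level backend failure (unknown profile, bad transcript)."""


class TranscriptError(BackendError):
    """A transcript file is malformed or ambiguous."""


@dataclasses.dataclass(frozen=True)
class BackendRequest:
    prompt: str
    temperature: float = 0.0
    max_output_tokens: int = 4096
    profile: str = "default"

    def __post_init__(self) -> None:
        if not self.prompt:
            raise ValueError("prompt must be non-empty")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.max_output_tokens <= 0:
            raise ValueError("max_output_tokens must be positive")


@dataclasses.dataclass(frozen=True)
class BackendResponse:
    text: str
    finish_state: str = "complete"  # complete | truncated | refused | backend_error
    latency: float = 0.0

    def __post_init__(self) -> None:
        if self.finish_state == "complete" and not self.text:
            raise ValueError("a complete response must carry non-empty text")


@dataclasses.dataclass
class TranscriptEntry:
    """One matcher → response rule of a recorded transcript.

    ``matcher_kind`` is ``"exact"`` (SHA-256 of the normalized prompt) or
    ``"substring"`` (normalized pattern contained in the normalized prompt).
    ``max_uses`` limits how often the entry may answer; ``None`` means
    unlimited.  Finite ``max_uses`` on an earlier entry lets a later entry
    with the same matcher take over — the mechanism repair transcripts use
    to return broken code first and fixed code on regeneration.
    """

    matcher_kind: str
    matcher: str
    response: str
    max_uses: int | None = None

    def __post_init__(self) -> None:
        if self.matcher_kind not in ("exact", "substring"):
            raise TranscriptError(f"unknown matcher_kind: {self.matcher_kind!r}")
        if self.max_uses is not None and self.max_uses <= 0:
            raise TranscriptError("max_uses must be positive or null")


_WS_RE = re.compile(r"\s+")


def normalize_prompt(prompt: str, placeholders: dict[str, str] | None = None) -> str:
    """Whitespace-normalize a prompt and substitute run-specific tokens.

    ``placeholders`` maps placeholder names (e.g. ``WORKSPACE``) to the
    concrete run-specific strings they stand for; occurrences of the value
    are replaced by ``{NAME}`` before hashing/matching.
    """
    text = prompt
    if placeholders:
        # longest value first so nested paths substitute deterministically
        for name, value in sorted(placeholders.items(), key=lambda kv: -len(kv[1])):
            if value:
                text = text.replace(value, "{%s}" % name)
    return _WS_RE.sub(" ", text).strip()


def prompt_key(prompt: str, placeholders: dict[str, str] | None = None) -> str:
    """The exact-matcher key for a prompt: SHA-256 of its normalized form."""
    return hashlib.sha256(normalize_prompt(prompt, placeholders).encode()).hexdigest()


class Backend:
    """Abstract backend: subclasses implement :meth:`complete`."""

    def complete(self, request: BackendRequest) -> BackendResponse:
        raise NotImplementedError


def load_transcript(path: str | os.PathLike) -> list[TranscriptEntry]:
    """Load and validate a transcript file (JSON list of entries).

    An empty or whitespace-only file yields an empty transcript.  An entry
    is rejected as unreachable/ambiguous if an *earlier* entry has the same
    (kind, matcher) and unlimited uses.
    """
    text = Path(path).read_text()
    if not text.strip():
        return []
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise TranscriptError(f"transcript {path} is not valid JSON: {exc}") from exc
    if not isinstance(raw, list):
        raise TranscriptError(f"transcript {path} must be a JSON list")
    entries = [
        TranscriptEntry(
            matcher_kind=item.get("matcher_kind", "substring"),
            matcher=item["matcher"],
            response=item["response"],
            max_uses=item.get("max_uses"),
        )
        for item in raw
    ]
    _validate_unambiguous(entries)
    return entries


def _validate_unambiguous(entries: Sequence[TranscriptEntry]) -> None:
    unlimited_seen: dict[tuple[str, str], int] = {}
    for i, e in enumerate(entries):
        key = (e.matcher_kind, e.matcher)
        if key in unlimited_seen:
            j = unlimited_seen[key]
            raise TranscriptError(
                f"ambiguous transcript: entry {i} duplicates the matcher of entry {j} "
                f"({e.matcher!r}) and entry {j} has unlimited uses, so entry {i} is unreachable"
            )
        if e.max_uses is None:
            unlimited_seen[key] = i


def dump_transcript(entries: Sequence[TranscriptEntry], path: str | os.PathLike) -> None:
    payload = [
        {
            "matcher_kind": e.matcher_kind,
            "matcher": e.matcher,
            "response": e.response,
            "max_uses": e.max_uses,
        }
        for e in entries
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


class TranscriptBackend(Backend):
    """Deterministic replay backend answering from a transcript.

    Matching walks the entries in order and returns the first entry with
    remaining uses whose matcher matches the normalized prompt.  A prompt
    matching no entry yields a ``backend_error`` response whose text names
    the nearest matcher, to keep fixture debugging tractable.
    """

    def __init__(
        self,
        entries: Sequence[TranscriptEntry],
        placeholders: dict[str, str] | None = None,
    ) -> None:
        _validate_unambiguous(entries)
        self._entries = list(entries)
        self._uses = [0] * len(self._entries)
        self.placeholders = dict(placeholders or {})

    @classmethod
    def from_file(
        cls, path: str | os.PathLike, placeholders: dict[str, str] | None = None
    ) -> "TranscriptBackend":
        return cls(load_transcript(path), placeholders)

    def _matches(self, entry: TranscriptEntry, norm_prompt: str) -> bool:
        if entry.matcher_kind == "exact":
            return hashlib.sha256(norm_prompt.encode()).hexdigest() == entry.matcher
        return normalize_prompt(entry.matcher) in norm_prompt

    def complete(self, request: BackendRequest) -> BackendResponse:
        norm = normalize_prompt(request.prompt, self.placeholders)
        for i, entry in enumerate(self._entries):
            if entry.max_uses is not None and self._uses[i] >= entry.max_uses:
                continue
            if self._matches(entry, norm):
                self._uses[i] += 1
                return BackendResponse(text=entry.response, finish_state="complete")
        nearest = self._nearest(norm)
        diag = (
            "transcript backend: no entry matches the prompt"
            + (f"; nearest matcher: {nearest!r}" if nearest else " (transcript is empty)")
        )
        return BackendResponse(text=diag, finish_state="backend_error")

    def _nearest(self, norm_prompt: str) -> str | None:
        best, best_score = None, -1.0
        for entry in self._entries:
            probe = normalize_prompt(entry.matcher)
            score = difflib.SequenceMatcher(None, probe, norm_prompt[: max(len(probe) * 3, 200)]).ratio()
            if entry.matcher_kind == "substring" and probe in norm_prompt:
                score = 1.0  # matched but exhausted
            if score > best_score:
                best, best_score = entry.matcher, score
        return best


class OpenAIChatBackend(Backend):
    """Adapter for OpenAI-compatible chat-completions HTTP endpoints.

    Transient transport failures are retried with exponential backoff;
    model-side refusals are reported in ``finish_state``, never raised.
    """

    def __init__(
        self,
        model: str,
        base_url: str = "https://api.openai.com/v1",
        api_key_env: str = "OPENAI_API_KEY",
        max_retries: int = 3,
        backoff: float = 1.0,
        sleep: Callable[[float], None] = time.sleep,
    ) -> None:
        self.model = model
        self.base_url = base_url.rstrip("/")
        self.api_key_env = api_key_env
        self.max_retries = max_retries
        self.backoff = backoff
        self._sleep = sleep

    def complete(self, request: BackendRequest) -> BackendResponse:
        api_key = os.environ.get(self.api_key_env, "")
        if not api_key:
            return BackendResponse(
                text=f"no API key in ${self.api_key_env}", finish_state="backend_error"
            )
        payload = json.dumps(
            {
                "model": self.model,
                "temperature": request.temperature,
                "max_tokens": request.max_output_tokens,
                "messages": [{"role": "user", "content": request.prompt}],
            }
        ).encode()
        req = urllib.request.Request(
            f"{self.base_url}/chat/completions",
            data=payload,
            headers={
                "Content-Type": "application/json",
                "Authorization": f"Bearer {api_key}",
            },
        )
        start = time.monotonic()
        last_err = ""
        for attempt in range(self.max_retries + 1):
            try:
                with urllib.request.urlopen(req, timeout=120) as resp:
                    body = json.loads(resp.read().decode())
                choice = body["choices"][0]
                finish = choice.get("finish_reason", "stop")
                state = {"stop": "complete", "length": "truncated"}.get(finish, "refused")
                return BackendResponse(
                    text=choice["message"]["content"] or "",
                    finish_state=state if choice["message"]["content"] else "refused",
                    latency=time.monotonic() - start,
                )
            except (urllib.error.URLError, TimeoutError, KeyError, json.JSONDecodeError) as exc:
                last_err = str(exc)
                if attempt < self.max_retries:
                    self._sleep(self.backoff * (2**attempt))
        return BackendResponse(
            text=f"transport failed after {self.max_retries + 1} attempts: {last_err}",
            finish_state="backend_error",
            latency=time.monotonic() - start,
        )


class LocalCommandBackend(Backend):
    """Adapter for a local instruct model wrapped as a subprocess.

    The command receives the prompt on stdin and must print the completion
    to stdout; temperature and token limit are exported as environment
    variables for the wrapper to honour.
    """

    def __init__(self, command: Sequence[str], timeout: float = 600.0) -> None:
        if not command:
            raise BackendError("local backend requires a non-empty command")
        self.command = list(command)
        self.timeout = timeout

    def complete(self, request: BackendRequest) -> BackendResponse:
        env = dict(
            os.environ,
            BIOPILOT_TEMPERATURE=str(request.temperature),
            BIOPILOT_MAX_TOKENS=str(request.max_output_tokens),
        )
        start = time.monotonic()
        try:
            proc = subprocess.run(
                self.command,
                input=request.prompt,
                capture_output=True,
                text=True,
                timeout=self.timeout,
                env=env,
            )
        except (OSError, subprocess.TimeoutExpired) as exc:
            return BackendResponse(
                text=f"local backend failed: {exc}",
                finish_state="backend_error",
                latency=time.monotonic() - start,
            )
        if proc.returncode != 0 or not proc.stdout:
            return BackendResponse(
                text=proc.stderr.strip() or f"exit status {proc.returncode}",
                finish_state="backend_error",
                latency=time.monotonic() - start,
            )
        return BackendResponse(
            text=proc.stdout, finish_state="complete", latency=time.monotonic() - start
        )


def resolve_backend(
    profile: str,
    transcript: str | os.PathLike | Sequence[TranscriptEntry] | None = None,
    placeholders: dict[str, str] | None = None,
) -> Backend:
    """Instantiate a backend from a profile identifier.

    Profiles: ``transcript`` (requires ``transcript``), ``openai:<model>``,
    and ``local:<command>`` (shell-split).  Unknown profiles raise
    :class:`BackendError`.
    """
    if profile == "transcript":
        if transcript is None:
            raise BackendError("profile 'transcript' requires a transcript file or entries")
        if isinstance(transcript, (str, os.PathLike)):
            return TranscriptBackend.from_file(transcript, placeholders)
        return TranscriptBackend(transcript, placeholders)
    if profile.startswith("openai:"):
        return OpenAIChatBackend(model=profile.split(":", 1)[1])
    if profile.startswith("local:"):
        import shlex

        return LocalCommandBackend(shlex.split(profile.split(":", 1)[1]))
    raise BackendError(f"unknown backend profile: {profile!r}")
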
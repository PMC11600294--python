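"""Analysis planning: obtain, parse and police the step-by-step plan.

The backend's planner output is free text; two splitters turn it into
ordered steps — explicit numbering (``1.`` / ``2)``) and ordinal
connectives (``First, … Next, … Then, … After that, … Finally, …``), both
styles occurring in real planner output.  Whichever splitter recognizes
more steps wins; on a tie the numbered parse is taken as the more explicit
one.  Software names are extracted per step from quoted tokens plus a
seeded lexicon of common bioinformatics tools, and file paths by pattern.

The user's blacklist is enforced twice: injected into the planning prompt,
and checked post-hoc against the parsed plan (:func:`check_blacklist`) so
that prohibited software triggers a re-proposal rather than silently
slipping through.
"""

from __future__ import annotations

import dataclasses
import re
from importlib import resources
from typing import Sequence

from .backends import Backend, BackendRequest
from .prompts import HistoryRecord, PromptContext, render_planning_prompt

__all__ = [
    "PlanParseError",
    "PlanningError",
    "PlanStep",
    "Plan",
    "parse_plan",
    "propose_plan",
    "check_blacklist",
    "load_tool_lexicon",
]


class PlanParseError(ValueError):
    """No steps could be recognized in planner output."""


class PlanningError(RuntimeError):
    """Planning failed after all re-asks; carries every raw response."""

    def __init__(self, message: str, responses: list[str]):
        super().__init__(message)
        self.responses = responses


@dataclasses.dataclass(frozen=True)
class PlanStep:
    index: int  # 1-based, consecutive
    description: str
    software: tuple[str, ...] = ()
    inputs_mentioned: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "description": self.description,
            "software": list(self.software),
            "inputs_mentioned": list(self.inputs_mentioned),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlanStep":
        return cls(
            index=d["index"],
            description=d["description"],
            software=tuple(d.get("software", ())),
            inputs_mentioned=tuple(d.get("inputs_mentioned", ())),
        )


@dataclasses.dataclass(frozen=True)
class Plan:
    steps: tuple[PlanStep, ...]
    raw_text: str

    def to_dict(self) -> dict:
        return {"steps": [s.to_dict() for s in self.steps], "raw_text": self.raw_text}

    @classmethod
    def from_dict(cls, d: dict) -> "Plan":
        return cls(
            steps=tuple(PlanStep.from_dict(s) for s in d["steps"]),
            raw_text=d["raw_text"],
        )


def load_tool_lexicon() -> tuple[str, ...]:
    """The bundled lexicon of known tool names (extensible data file)."""
    text = resources.files("biopilot.data").joinpath("tool_lexicon.txt").read_text()
    return tuple(
        line.strip() for line in text.splitlines() if line.strip() and not line.startswith("#")
    )


_NUMBERED_RE = re.compile(r"(?:^|\n)\s*(\d+)[.)]\s+", re.MULTILINE)
# Ordinal connectives open a step when they follow the text start, a newline,
# or a sentence-ending period/quote.
_ORDINAL_RE = re.compile(
    r"(?:(?<=^)|(?<=\n)|(?<=[.!?])|(?<=[.!?][\"'”]))\s*"
    r"((?:First|Next|Then|After that|Finally|Second|Third|Fourth|Fifth|Lastly)\b,?\s+)",
)
_QUOTED_RE = re.compile(r"[\"“]([^\"“”]{1,60})[\"”]|'([A-Za-z][\w .+-]{1,40})'")
_PATH_RE = re.compile(
    r"(?:\.{0,2}/[\w.+-]+(?:/[\w.+-]+)*"  # ./x, ../x, /x, possibly nested
    r"|\b[\w.+-]+\.(?:fastq|fq|fasta|fa|fna|gtf|gff3?|bam|sam|cram|vcf|bed|csv|tsv|txt)(?:\.gz)?\b)"
)


def _split_numbered(text: str) -> list[str]:
    marks = list(_NUMBERED_RE.finditer(text))
    if not marks:
        return []
    parts = []
    for i, m in enumerate(marks):
        end = marks[i + 1].start() if i + 1 < len(marks) else len(text)
        parts.append(text[m.end() : end].strip())
    return [p for p in parts if p]


def _split_ordinal(text: str) -> list[str]:
    marks = list(_ORDINAL_RE.finditer(text))
    if not marks:
        return []
    parts = []
    for i, m in enumerate(marks):
        start = m.start(1)
        end = marks[i + 1].start(1) if i + 1 < len(marks) else len(text)
        parts.append(text[start:end].strip())
    return [p for p in parts if p]


def _extract_software(segment: str, lexicon: Sequence[str]) -> tuple[str, ...]:
    found: list[str] = []

    def add(name: str) -> None:
        name = name.strip().strip(".,;:")
        if name and name.casefold() not in {f.casefold() for f in found}:
            found.append(name)

    for m in _QUOTED_RE.finditer(segment):
        token = m.group(1) or m.group(2)
        # quoted tokens are kept as software if tool-like (no sentence-y text)
        if token and len(token.split()) <= 3 and not token.endswith("."):
            add(token)
    seg_fold = segment.casefold()
    for tool in sorted(lexicon, key=len, reverse=True):
        pat = r"(?<![\w.])" + re.escape(tool.casefold()) + r"(?![\w])"
        if re.search(pat, seg_fold):
            add(tool)
    return tuple(found)


def _extract_paths(segment: str) -> tuple[str, ...]:
    out: list[str] = []
    for m in _PATH_RE.finditer(segment):
        token = m.group(0).rstrip(".,;:")
        if token not in out:
            out.append(token)
    return tuple(out)


def parse_plan(text: str, lexicon: Sequence[str] | None = None) -> Plan:
    """Parse planner output into an ordered, software-annotated plan.

    Raises :class:`PlanParseError` when neither splitter recognizes a step.
    """
    if lexicon is None:
        lexicon = load_tool_lexicon()
    numbered = _split_numbered(text)
    ordinal = _split_ordinal(text)
    # more steps wins; tie → numbered (more explicit)
    segments = numbered if len(numbered) >= len(ordinal) else ordinal
    if not segments:
        raise PlanParseError(
            "no plan steps recognized (no numbering and no ordinal connectives) in: "
            + text[:500]
        )
    steps = tuple(
        PlanStep(
            index=i,
            description=seg,
            software=_extract_software(seg, lexicon),
            inputs_mentioned=_extract_paths(seg),
        )
        for i, seg in enumerate(segments, start=1)
    )
    return Plan(steps=steps, raw_text=text)


def propose_plan(
    backend: Backend,
    ctx: PromptContext,
    max_repair_attempts: int = 5,
    temperature: float = 0.0,
    history: list[HistoryRecord] | None = None,
    diagnostic: str | None = None,
) -> Plan:
    """Ask the backend for a plan, re-asking with the parse diagnostic on
    failure, bounded by ``max_repair_attempts`` re-asks.

    On success the accepted plan is recorded as the run's ``input_and_plan``
    history record when a ``history`` list is supplied.
    """
    responses: list[str] = []
    diag = diagnostic
    for _ in range(max_repair_attempts + 1):
        prompt = render_planning_prompt(ctx, diagnostic=diag)
        resp = backend.complete(BackendRequest(prompt=prompt, temperature=temperature))
        responses.append(resp.text)
        if resp.finish_state != "complete":
            diag = f"backend returned {resp.finish_state}: {resp.text[:500]}"
            continue
        try:
            plan = parse_plan(resp.text)
        except PlanParseError as exc:
            diag = f"your previous answer could not be parsed as a plan: {exc}"
            continue
        if history is not None:
            history.append(
                HistoryRecord(
                    kind="input_and_plan",
                    global_goal=ctx.current_goal,
                    data_entries=tuple(ctx.data_list),
                    plan_tasks=tuple(s.description for s in plan.steps),
                )
            )
        return plan
    raise PlanningError(
        f"planning failed after {max_repair_attempts + 1} attempt(s)", responses
    )


def check_blacklist(plan: Plan, blacklist: Sequence[str]) -> list[tuple[int, str]]:
    """Every (step index, software) pair whose software case-insensitively
    matches a blacklist entry.  A non-empty result means the plan must be
    rejected and re-proposed."""
    folded = {b.casefold() for b in blacklist}
    violations: list[tuple[int, str]] = []
    for step in plan.steps:
        for sw in step.software:
            if sw.casefold() in folded:
                violations.append((step.index, sw))
    return violations
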
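"""Prompt construction and agent memory.

Every backend call is stateless: the full context is re-rendered into each
prompt from four named slots — the software *blacklist*, the ordered *data
list* of ``path: description`` pairs, the *current goal* (the global
objective during planning, the step's sub-goal during code generation), and
the *history summary*, a natural-language memory of what the agent has done
so far.

The history summary is assembled from two fixed sentence templates: one
describing the original input and the accepted plan, and one appended per
successfully completed task.  When the summary would exceed the context
budget, the oldest completed-task sentences are elided (the plan sentence is
always retained) and replaced by a count marker.

Prompts use ``=== SECTION ===`` delimiters; slot values are escaped so that
a value containing a delimiter line cannot break the section structure, and
:func:`extract_slots` recovers all four slots from a rendered prompt.
"""

from __future__ import annotations

import dataclasses
import re
from importlib import resources
from typing import Iterable, Sequence

from .config import DataEntry

__all__ = [
    "HistoryRecord",
    "PromptContext",
    "HistoryOrderError",
    "PLAN_MEMORY_TEMPLATE",
    "TASK_MEMORY_TEMPLATE",
    "EMPTY_BLACKLIST_MARKER",
    "EMPTY_HISTORY_MARKER",
    "summarize_history",
    "render_planning_prompt",
    "render_codegen_prompt",
    "render_repair_prompt",
    "extract_slots",
]

# Memory sentence templates (fixed wording; slot names in angle brackets in
# the docs map to the format fields below).
PLAN_MEMORY_TEMPLATE = (
    "First, you provided input in the format 'file path: file description' "
    "in a list: {data_list}. You devised a detailed plan to accomplish your "
    "overarching objective. Your overarching goal is {global_goal}. "
    "Your plan involves {tasks}."
)
TASK_MEMORY_TEMPLATE = (
    "Then, you successfully completed the task: {task} "
    "with the corresponding code: {code}."
)

EMPTY_BLACKLIST_MARKER = "none"
EMPTY_HISTORY_MARKER = "no prior actions"

# Character-count proxy for tokens: ~4 characters per token.
CHARS_PER_TOKEN = 4


class HistoryOrderError(ValueError):
    """History records violate the ordering contract."""


@dataclasses.dataclass(frozen=True)
class HistoryRecord:
    """One unit of agent memory.

    ``kind`` is ``input_and_plan`` (exactly one per run, first) or
    ``task_completed`` (one per successfully executed step, in order).
    """

    kind: str
    global_goal: str = ""
    data_entries: tuple[DataEntry, ...] = ()
    plan_tasks: tuple[str, ...] = ()
    task: str = ""
    code: str = ""
    timestamp: float = 0.0


@dataclasses.dataclass(frozen=True)
class PromptContext:
    """The four named prompt slots, always all present."""

    blacklist: tuple[str, ...]
    data_list: tuple[DataEntry, ...]
    current_goal: str
    history_summary: str


def _validate_order(records: Sequence[HistoryRecord]) -> None:
    for i, rec in enumerate(records):
        if rec.kind not in ("input_and_plan", "task_completed"):
            raise HistoryOrderError(f"unknown record kind: {rec.kind!r}")
        if rec.kind == "input_and_plan" and i != 0:
            raise HistoryOrderError("input_and_plan record must be first and unique")
    if records and records[0].kind != "input_and_plan":
        raise HistoryOrderError("history must start with the input_and_plan record")


def _plan_sentence(rec: HistoryRecord) -> str:
    data_list = ", ".join(e.render() for e in rec.data_entries)
    tasks = "; ".join(
        f"({i}) {t}" for i, t in enumerate(rec.plan_tasks, start=1)
    )
    return PLAN_MEMORY_TEMPLATE.format(
        data_list=data_list, global_goal=rec.global_goal, tasks=tasks
    )


def _task_sentence(rec: HistoryRecord) -> str:
    return TASK_MEMORY_TEMPLATE.format(task=rec.task, code=rec.code)


def summarize_history(
    records: Sequence[HistoryRecord], token_budget: int | None = None
) -> str:
    """Render history records into the natural-language memory string.

    With no records the summary is empty.  Under a ``token_budget`` the
    oldest completed-task sentences are elided oldest-first and replaced by
    a single count marker; the plan sentence and the most recent task
    sentence are always retained even if the budget is exceeded.
    """
    _validate_order(records)
    if not records:
        return ""
    sentences = [_plan_sentence(records[0])]
    task_sentences = [_task_sentence(r) for r in records[1:]]

    if token_budget is None:
        return " ".join(sentences + task_sentences)

    char_budget = token_budget * CHARS_PER_TOKEN
    kept = list(task_sentences)
    elided = 0
    while kept:
        marker = [f"[{elided} earlier completed tasks elided.]"] if elided else []
        text = " ".join(sentences + marker + kept)
        if len(text) <= char_budget or len(kept) == 1:
            return text
        kept.pop(0)
        elided += 1
    marker = [f"[{elided} earlier completed tasks elided.]"] if elided else []
    return " ".join(sentences + marker)


# ---------------------------------------------------------------------------
# Prompt rendering

_SECTION_RE = re.compile(r"^=== ([A-Z ]+) ===$")
_ESCAPABLE_RE = re.compile(r"^(\\*)(=== )")


def _escape_slot(text: str) -> str:
    """Escape lines that would read as section delimiters inside a slot."""
    out = []
    for line in text.split("\n"):
        m = _ESCAPABLE_RE.match(line)
        out.append("\\" + line if m else line)
    return "\n".join(out)


def _unescape_slot(text: str) -> str:
    """Exact inverse of :func:`_escape_slot`."""
    out = []
    for line in text.split("\n"):
        if line.startswith("\\") and _ESCAPABLE_RE.match(line[1:]):
            line = line[1:]
        out.append(line)
    return "\n".join(out)


def _load_template(name: str) -> str:
    return resources.files("biopilot.templates").joinpath(name).read_text()


def _slot_values(ctx: PromptContext) -> dict[str, str]:
    blacklist = "\n".join(ctx.blacklist) if ctx.blacklist else EMPTY_BLACKLIST_MARKER
    data_list = "\n".join(e.render() for e in ctx.data_list)
    history = ctx.history_summary if ctx.history_summary else EMPTY_HISTORY_MARKER
    return {
        "blacklist": _escape_slot(blacklist),
        "data_list": _escape_slot(data_list),
        "current_goal": _escape_slot(ctx.current_goal),
        "history_summary": _escape_slot(history),
    }


def render_planning_prompt(ctx: PromptContext, diagnostic: str | None = None) -> str:
    """Render the planning-phase prompt from the four slots.

    ``diagnostic`` appends feedback from a failed previous proposal (parse
    diagnostics or blacklist violations) so the backend can re-plan.
    """
    if not ctx.current_goal.strip():
        raise ValueError("planning context requires a non-empty current goal")
    text = _load_template("planning.txt").format(**_slot_values(ctx))
    if diagnostic:
        text += (
            "\n=== DIAGNOSTIC ===\n"
            + _escape_slot(diagnostic)
            + "\nRevise the plan to address the diagnostic above.\n"
        )
    return text


def render_codegen_prompt(ctx: PromptContext, step, diagnostic: str | None = None) -> str:
    """Render the code-generation prompt for one plan step.

    ``ctx.current_goal`` must equal the step's description (the sub-goal).
    """
    if not step.description.strip():
        raise ValueError("plan step has an empty description")
    if ctx.current_goal != step.description:
        raise ValueError("codegen context current_goal must equal the step description")
    software = ", ".join(step.software) if step.software else "none specified"
    values = dict(_slot_values(ctx), software=_escape_slot(software))
    text = _load_template("codegen.txt").format(**values)
    if diagnostic:
        text += (
            "\n=== DIAGNOSTIC ===\n"
            + _escape_slot(diagnostic)
            + "\nYour previous answer could not be used; follow the instructions exactly.\n"
        )
    return text


def render_repair_prompt(
    ctx: PromptContext, step, previous_code: str, error_excerpt: str
) -> str:
    """Codegen prompt plus the previous attempt and its observed error."""
    suffix = _load_template("repair_suffix.txt").format(
        previous_code=_escape_slot(previous_code),
        error_excerpt=_escape_slot(error_excerpt),
    )
    return render_codegen_prompt(ctx, step) + suffix


# ---------------------------------------------------------------------------
# Slot re-extraction (round-trip oracle surface)

_SLOT_SECTIONS = {"BLACKLIST", "DATA LIST", "CURRENT GOAL", "HISTORY SUMMARY"}


def extract_slots(prompt_text: str) -> PromptContext:
    """Recover the four named slots from a rendered prompt.

    Inverse of the renderers modulo the documented empty-slot markers: an
    empty blacklist renders as ``none`` and an empty history as
    ``no prior actions``, so those literal values round-trip to empty.
    """
    sections: dict[str, list[str]] = {}
    current: str | None = None
    for line in prompt_text.split("\n"):
        m = _SECTION_RE.match(line)
        if m:
            current = m.group(1)
            sections[current] = []
        elif current is not None:
            sections[current].append(line)
    missing = _SLOT_SECTIONS - set(sections)
    if missing:
        raise ValueError(f"prompt is missing slot section(s): {sorted(missing)}")

    def body(name: str) -> str:
        text = "\n".join(sections[name])
        return _unescape_slot(text).strip("\n")

    raw_blacklist = body("BLACKLIST")
    blacklist: tuple[str, ...] = (
        () if raw_blacklist == EMPTY_BLACKLIST_MARKER else tuple(raw_blacklist.split("\n"))
    )
    entries = []
    data_body = body("DATA LIST")
    for line in data_body.split("\n") if data_body else []:
        path, _, desc = line.partition(": ")
        entries.append(DataEntry(path=path, description=desc))
    history = body("HISTORY SUMMARY")
    if history == EMPTY_HISTORY_MARKER:
        history = ""
    return PromptContext(
        blacklist=blacklist,
        data_list=tuple(entries),
        current_goal=body("CURRENT GOAL"),
        history_summary=history,
    )
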
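"""Shell code generation and the automatic code repair (ACR) cycle.

For each plan step the agent renders a code-generation prompt, extracts a
shell script from the backend's answer, and hands it to the executor.  When
execution is classified as an error, a bounded excerpt of the error text
(tail-biased — shell errors usually trail) is appended to the prompt and
the whole script is regenerated, repeating until the code runs clean or the
attempt bound is exhausted.  Repair is whole-script regeneration; there is
no AST-level patching.
"""

from __future__ import annotations

import dataclasses
import re
from typing import Callable, Sequence

from .backends import Backend, BackendRequest
from .executor import ErrorFinding, ExecutionResult
from .planner import PlanStep
from .prompts import PromptContext, render_codegen_prompt, render_repair_prompt
from .runlog import NullLog

__all__ = [
    "ExtractionError",
    "CodegenError",
    "CodeBlock",
    "RepairAttempt",
    "extract_code",
    "generate_code",
    "repair_loop",
    "ERROR_EXCERPT_LIMIT",
]

# Max characters of error text fed back into the repair prompt.
ERROR_EXCERPT_LIMIT = 4000


class ExtractionError(ValueError):
    """No shell code could be extracted from a backend response."""


class CodegenError(RuntimeError):
    """Code generation failed after all re-asks; carries every raw response."""

    def __init__(self, message: str, responses: list[str]):
        super().__init__(message)
        self.responses = responses


@dataclasses.dataclass(frozen=True)
class CodeBlock:
    step_index: int
    shell_text: str
    attempt: int = 1  # 1-based
    source_response: str = ""

    def __post_init__(self) -> None:
        if not self.shell_text.strip():
            raise ValueError("shell_text must be non-empty")
        if self.attempt < 1:
            raise ValueError("attempt is 1-based")


@dataclasses.dataclass(frozen=True)
class RepairAttempt:
    attempt: int
    code: CodeBlock
    result: ExecutionResult | None
    error_excerpt: str = ""

    @property
    def succeeded(self) -> bool:
        return not self.error_excerpt


_FENCE_RE = re.compile(r"```([^\n`]*)\n(.*?)```", re.DOTALL)
_SHELL_TAGS = {"", "bash", "sh", "shell", "zsh", "console"}

# Command-likeness heuristic for unfenced responses.
_COMMAND_WORDS = {
    "cd", "ls", "echo", "cat", "cp", "mv", "rm", "mkdir", "touch", "gzip",
    "gunzip", "tar", "source", "export", "set", "conda", "pip", "python",
    "python3", "Rscript", "bash", "sh", "for", "while", "if", "fi", "done",
    "then", "else", "wget", "curl", "samtools", "bcftools", "bedtools",
    "bwa", "bowtie2", "hisat2", "hisat2-build", "minimap2", "trimmomatic",
    "cutadapt", "fastqc", "macs2", "htseq-count", "featureCounts", "stringtie",
    "exit", "true", "false", "sleep", "head", "tail", "sort", "grep", "awk",
    "sed", "chmod", "make",
}


def _looks_like_command(line: str) -> bool:
    stripped = line.strip()
    if stripped.startswith(("#", "./", "/", "$", "~")):
        return True
    first = stripped.split()[0] if stripped.split() else ""
    return first in _COMMAND_WORDS or "=" in first


def extract_code(response_text: str) -> str:
    """Extract shell code from a backend response.

    All fenced blocks tagged as shell (or untagged) are concatenated in
    order.  Without fences, the whole text is accepted when at least 80% of
    its non-empty lines look like commands; otherwise extraction fails and
    the diagnostic feeds a re-ask.
    """
    blocks = [
        body for tag, body in _FENCE_RE.findall(response_text)
        if tag.strip().lower() in _SHELL_TAGS
    ]
    if blocks:
        return "\n".join(b.strip("\n") for b in blocks)
    lines = [ln for ln in response_text.split("\n") if ln.strip()]
    if lines:
        commandish = sum(1 for ln in lines if _looks_like_command(ln))
        if commandish / len(lines) >= 0.8:
            return response_text.strip("\n")
    raise ExtractionError(
        "no fenced shell code block found and the text does not look like shell commands"
    )


def generate_code(
    backend: Backend,
    ctx: PromptContext,
    step: PlanStep,
    max_repair_attempts: int = 5,
    temperature: float = 0.0,
    log=None,
) -> CodeBlock:
    """Render the codegen prompt, call the backend, extract the script.

    Extraction failures (and refusals) are fed back as diagnostics, bounded
    by ``max_repair_attempts`` re-asks.
    """
    log = log or NullLog()
    responses: list[str] = []
    diag: str | None = None
    for _ in range(max_repair_attempts + 1):
        prompt = render_codegen_prompt(ctx, step, diagnostic=diag)
        resp = backend.complete(BackendRequest(prompt=prompt, temperature=temperature))
        log.append("backend_response", phase="codegen", step=step.index,
                   finish_state=resp.finish_state, text=resp.text)
        responses.append(resp.text)
        if resp.finish_state != "complete":
            diag = f"backend returned {resp.finish_state}: {resp.text[:500]}"
            continue
        try:
            shell = extract_code(resp.text)
        except ExtractionError as exc:
            diag = str(exc)
            continue
        return CodeBlock(step_index=step.index, shell_text=shell,
                         attempt=1, source_response=resp.text)
    raise CodegenError(
        f"code generation for step {step.index} failed after "
        f"{max_repair_attempts + 1} attempt(s)",
        responses,
    )


def _bounded_excerpt(finding: ErrorFinding) -> str:
    return finding.excerpt[-ERROR_EXCERPT_LIMIT:]


def repair_loop(
    backend: Backend,
    ctx: PromptContext,
    step: PlanStep,
    initial: CodeBlock,
    executor: Callable[[CodeBlock], tuple[ExecutionResult | None, ErrorFinding]],
    max_repair_attempts: int = 5,
    temperature: float = 0.0,
    log=None,
) -> tuple[ExecutionResult | None, list[RepairAttempt]]:
    """Execute-and-repair until success or exhaustion of the attempt bound.

    ``executor`` runs one code block and returns its execution result (None
    when the script was rejected before execution) together with the error
    classification.  Each regeneration appends the previous code and a
    bounded error excerpt to the codegen prompt.  The attempts list has at
    most ``max_repair_attempts + 1`` elements; exhaustion is a reported
    outcome, never an exception.
    """
    log = log or NullLog()
    attempts: list[RepairAttempt] = []
    code = initial
    for attempt_no in range(1, max_repair_attempts + 2):
        result, finding = executor(code)
        excerpt = _bounded_excerpt(finding) if finding.is_error else ""
        attempts.append(RepairAttempt(attempt=attempt_no, code=code,
                                      result=result, error_excerpt=excerpt))
        log.append("repair_attempt", step=step.index, attempt=attempt_no,
                   is_error=finding.is_error, reason=finding.reason,
                   excerpt=excerpt[:500],
                   result=result.to_dict() if result is not None else None)
        if not finding.is_error:
            return result, attempts
        if attempt_no > max_repair_attempts:
            break
        prompt = render_repair_prompt(ctx, step, code.shell_text, excerpt)
        resp = backend.complete(BackendRequest(prompt=prompt, temperature=temperature))
        log.append("backend_response", phase="repair", step=step.index,
                   finish_state=resp.finish_state, text=resp.text)
        if resp.finish_state != "complete":
            # a dead backend cannot repair anything; count remaining budget down
            continue
        try:
            shell = extract_code(resp.text)
        except ExtractionError:
            continue
        code = CodeBlock(step_index=step.index, shell_text=shell,
                         attempt=attempt_no + 1, source_response=resp.text)
    return attempts[-1].result, attempts
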
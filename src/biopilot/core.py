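"""Run orchestration: plan → per-step codegen → screen → execute → repair.

A run proceeds in three phases.  The planning phase asks the backend for an
ordered analysis plan and enforces the blacklist (violations trigger a
bounded re-proposal loop).  Then, for each step in order, the code
generation phase produces a shell script and the execution phase screens
and runs it inside the workspace, with the automatic repair cycle driving
regeneration on classified errors.  A successfully completed step is
appended to the agent's memory; a step that exhausts its repair budget
stops the run and the remaining steps are marked skipped (downstream
bioinformatics steps consume upstream outputs, so continuing would be
meaningless).  Every run always yields a :class:`RunReport`, written to the
workspace logs.
"""

from __future__ import annotations

import dataclasses
import time
from pathlib import Path
from typing import Any

import json

from .backends import Backend
from .codegen import CodeBlock, CodegenError, generate_code, repair_loop
from .config import AnalysisConfig, Workspace, init_workspace
from .executor import SandboxPolicy, default_denylist, detect_error, execute, screen_commands
from .planner import Plan, PlanningError, check_blacklist, propose_plan
from .prompts import HistoryRecord, PromptContext, summarize_history
from .runlog import RunLog, read_events

__all__ = ["StepOutcome", "RunReport", "run_agent", "replay"]


@dataclasses.dataclass(frozen=True)
class StepOutcome:
    index: int
    description: str
    status: str  # success | failed | skipped
    attempts: int
    final_result: str | None = None  # workspace-relative path to the result JSON

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StepOutcome":
        return cls(**d)


@dataclasses.dataclass(frozen=True)
class RunReport:
    run_id: str
    plan: Plan | None
    step_outcomes: tuple[StepOutcome, ...]
    stage_flags: dict[str, bool]
    started: float
    ended: float
    aborted: bool = False

    def to_dict(self) -> dict:
        return {
            "run_id": self.run_id,
            "plan": self.plan.to_dict() if self.plan else None,
            "step_outcomes": [o.to_dict() for o in self.step_outcomes],
            "stage_flags": dict(self.stage_flags),
            "started": self.started,
            "ended": self.ended,
            "aborted": self.aborted,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunReport":
        return cls(
            run_id=d["run_id"],
            plan=Plan.from_dict(d["plan"]) if d.get("plan") else None,
            step_outcomes=tuple(StepOutcome.from_dict(o) for o in d["step_outcomes"]),
            stage_flags=dict(d["stage_flags"]),
            started=d["started"],
            ended=d["ended"],
            aborted=d.get("aborted", False),
        )

    def canonical_dict(self) -> dict:
        """Report content with volatile fields (timestamps, run id) removed,
        for byte-level reproducibility comparisons."""
        d = self.to_dict()
        d.pop("started"), d.pop("ended"), d.pop("run_id")
        return d


def _stage_flags(plan_ok: bool, outcomes: list[StepOutcome], n_steps: int) -> dict[str, bool]:
    # codegen is "ok" for a step once at least one script was produced
    # (attempts >= 1); skipped steps and codegen-exhausted steps break it.
    all_codegen_ok = (
        plan_ok
        and n_steps > 0
        and len(outcomes) == n_steps
        and all(o.attempts >= 1 for o in outcomes)
    )
    end_to_end_ok = plan_ok and bool(outcomes) and all(o.status == "success" for o in outcomes)
    return {
        "plan_ok": plan_ok,
        "all_codegen_ok": bool(all_codegen_ok),
        "end_to_end_ok": bool(end_to_end_ok),
    }


def run_agent(
    config: AnalysisConfig,
    backend: Backend,
    workspace: Workspace | None = None,
    run_id: str | None = None,
    overwrite: bool = False,
    policy: SandboxPolicy | None = None,
    env_extra: dict[str, str] | None = None,
    history_token_budget: int | None = None,
) -> RunReport:
    """Execute a full agent run and return (and persist) its report.

    ``env_extra`` is merged into the execution environment (used by offline
    fixtures to put stub tools on PATH).  ``history_token_budget`` caps the
    history summary re-rendered into every prompt.
    """
    started = time.time()
    if workspace is None:
        workspace = init_workspace(config, run_id=run_id, overwrite=overwrite)
    if policy is None:
        policy = SandboxPolicy(
            denylist=default_denylist(workspace.root), timeout=config.step_timeout
        )
    log = RunLog(Path(workspace.logs_dir) / "events.jsonl")
    log.append("run_started", run_id=workspace.run_id, started=started,
               goal=config.global_goal, n_data=len(config.data_entries))

    history: list[HistoryRecord] = []
    blacklist = tuple(config.blacklist)
    data_list = tuple(config.data_entries)

    def ctx_for(goal: str) -> PromptContext:
        return PromptContext(
            blacklist=blacklist,
            data_list=data_list,
            current_goal=goal,
            history_summary=summarize_history(history, token_budget=history_token_budget),
        )

    # --- planning phase, with blacklist re-proposal loop -------------------
    plan: Plan | None = None
    plan_ok = False
    diagnostic: str | None = None
    logging_backend = _LoggingBackend(backend, log)
    try:
        for _ in range(config.max_repair_attempts + 1):
            candidate = propose_plan(
                logging_backend,
                ctx_for(config.global_goal),
                max_repair_attempts=config.max_repair_attempts,
                temperature=config.decoding_temperature,
                diagnostic=diagnostic,
            )
            violations = check_blacklist(candidate, blacklist)
            if not violations:
                plan = candidate
                plan_ok = True
                break
            log.append("plan_rejected", violations=violations)
            diagnostic = "the plan used blacklisted software: " + ", ".join(
                f"step {i}: {sw}" for i, sw in violations
            )
        if plan is None and diagnostic is not None:
            log.append("planning_failed", reason="blacklist re-proposals exhausted")
    except PlanningError as exc:
        log.append("planning_failed", reason=str(exc), responses=exc.responses)

    if not plan_ok or plan is None:
        ended = time.time()
        report = RunReport(
            run_id=workspace.run_id, plan=None, step_outcomes=(),
            stage_flags=_stage_flags(False, [], 0), started=started, ended=ended,
        )
        _finish(log, report, workspace)
        return report

    history.append(
        HistoryRecord(
            kind="input_and_plan",
            global_goal=config.global_goal,
            data_entries=data_list,
            plan_tasks=tuple(s.description for s in plan.steps),
        )
    )
    log.append("plan_accepted", plan=plan.to_dict())

    # --- per-step codegen / execution / repair ------------------------------
    outcomes: list[StepOutcome] = []
    failed = False
    for step in plan.steps:
        if failed:
            outcomes.append(StepOutcome(index=step.index, description=step.description,
                                        status="skipped", attempts=0))
            log.append("step_skipped", step=step.index)
            continue
        ctx = ctx_for(step.description)
        try:
            initial = generate_code(
                logging_backend, ctx, step,
                max_repair_attempts=config.max_repair_attempts,
                temperature=config.decoding_temperature, log=log,
            )
        except CodegenError as exc:
            log.append("codegen_failed", step=step.index, responses=exc.responses)
            outcomes.append(StepOutcome(index=step.index, description=step.description,
                                        status="failed", attempts=0))
            failed = True
            log.append("step_finished", outcome=outcomes[-1].to_dict())
            continue

        def run_one(code: CodeBlock):
            decision = screen_commands(code.shell_text, policy)
            log.append("screen", step=code.step_index, attempt=code.attempt,
                       accepted=decision.accepted,
                       offenses=[list(o) for o in decision.offenses])
            if not decision.accepted:
                return None, decision.as_finding()
            result = execute(code, workspace, policy, env_extra=env_extra, audit_log=log)
            log.append("execution", step=code.step_index, attempt=code.attempt,
                       result=result.to_dict())
            return result, detect_error(result, policy.error_patterns)

        final_result, attempts = repair_loop(
            logging_backend, ctx, step, initial, run_one,
            max_repair_attempts=config.max_repair_attempts,
            temperature=config.decoding_temperature, log=log,
        )
        success = attempts[-1].succeeded
        rel_result = None
        last_with_result = next((a for a in reversed(attempts) if a.result is not None), None)
        if last_with_result is not None:
            rel_result = (
                f"scripts/step{step.index}_attempt{last_with_result.code.attempt}.result.json"
            )
        outcome = StepOutcome(
            index=step.index, description=step.description,
            status="success" if success else "failed",
            attempts=len(attempts), final_result=rel_result,
        )
        outcomes.append(outcome)
        log.append("step_finished", outcome=outcome.to_dict())
        if success:
            history.append(
                HistoryRecord(kind="task_completed", task=step.description,
                              code=attempts[-1].code.shell_text)
            )
        else:
            failed = True

    ended = time.time()
    report = RunReport(
        run_id=workspace.run_id, plan=plan, step_outcomes=tuple(outcomes),
        stage_flags=_stage_flags(True, outcomes, len(plan.steps)),
        started=started, ended=ended,
    )
    _finish(log, report, workspace)
    return report


def _finish(log: RunLog, report: RunReport, workspace: Workspace) -> None:
    log.append("run_finished", run_id=report.run_id, started=report.started,
               ended=report.ended, stage_flags=report.stage_flags,
               aborted=report.aborted)
    (Path(workspace.logs_dir) / "report.json").write_text(
        json.dumps(report.to_dict(), indent=2)
    )


class _LoggingBackend(Backend):
    """Wraps a backend so every request/response lands in the run log."""

    def __init__(self, inner: Backend, log: RunLog):
        self._inner = inner
        self._log = log

    def complete(self, request):
        self._log.append("backend_request", profile=request.profile,
                         temperature=request.temperature, prompt=request.prompt)
        resp = self._inner.complete(request)
        self._log.append("backend_reply", finish_state=resp.finish_state, text=resp.text)
        return resp


def replay(log_path: str | Path) -> RunReport:
    """Reconstruct the run report from a recorded event log.

    Nothing is re-executed: the plan, per-step outcomes and stage flags are
    rebuilt from the incremental events and must agree with what the live
    run returned.
    """
    plan: Plan | None = None
    outcomes: list[StepOutcome] = []
    run_id = ""
    started = ended = 0.0
    stage_flags: dict[str, bool] = {}
    aborted = False
    for ev in read_events(log_path):
        kind = ev["event"]
        if kind == "run_started":
            run_id, started = ev["run_id"], ev["started"]
        elif kind == "plan_accepted":
            plan = Plan.from_dict(ev["plan"])
        elif kind == "step_finished":
            outcomes.append(StepOutcome.from_dict(ev["outcome"]))
        elif kind == "run_finished":
            ended = ev["ended"]
            stage_flags = dict(ev["stage_flags"])
            aborted = ev.get("aborted", False)
    # skipped steps: fill from the plan for indices with no outcome
    if plan is not None:
        have = {o.index for o in outcomes}
        for step in plan.steps:
            if step.index not in have:
                outcomes.append(StepOutcome(index=step.index, description=step.description,
                                            status="skipped", attempts=0))
        outcomes.sort(key=lambda o: o.index)
    return RunReport(
        run_id=run_id, plan=plan, step_outcomes=tuple(outcomes),
        stage_flags=stage_flags, started=started, ended=ended, aborted=aborted,
    )
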
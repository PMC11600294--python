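"""The bundled 40-case evaluation registry and its summarizer.

Each record holds one real-world analysis case with expert-judged outcomes
for the three agent stages — proposing a plan, generating code, executing
it — for two variants: the bare agent (``no_acr``) and the agent with the
automatic code repair loop (``with_acr``).  Stage outcomes obey the
implication chain: execution success requires code-generation success
requires plan success.

For the with-repair variant some per-case cells are ``unknown`` (only
aggregate counts were published for it); the summarizer resolves those
against a bundled aggregate record after checking consistency with the
known cells.
"""

from __future__ import annotations

import csv
import dataclasses
import io
import json
from fractions import Fraction
from importlib import resources
from typing import Sequence

__all__ = [
    "RegistryError",
    "CaseRecord",
    "EvaluationSummary",
    "load_case_registry",
    "load_acr_aggregates",
    "summarize_evaluation",
]

STAGES = ("plan", "codegen", "execute")
OMICS_TYPES = ("genomics", "transcriptomics", "proteomics", "metabolomics")
_OUTCOMES = {"pass", "fail", "unknown"}


class RegistryError(ValueError):
    """A registry violates the schema or the stage-implication invariant."""


@dataclasses.dataclass(frozen=True)
class CaseRecord:
    case_id: str
    pipeline_class: str
    task: str
    omics_type: str
    outcomes: dict  # {"no_acr": {stage: pass/fail/unknown}, "with_acr": {...}}
    failure_reason: str
    tools_used: tuple[str, ...]
    time_cost_minutes: int

    def stage(self, variant: str, stage: str) -> str:
        return self.outcomes[variant][stage]


def _check_record(rec: CaseRecord) -> None:
    if rec.omics_type not in OMICS_TYPES:
        raise RegistryError(f"case {rec.case_id}: unknown omics type {rec.omics_type!r}")
    for variant, stages in rec.outcomes.items():
        vals = [stages[s] for s in STAGES]
        if any(v not in _OUTCOMES for v in vals):
            raise RegistryError(f"case {rec.case_id}: bad outcome value in {variant}")
        # implication chain on known cells: execute pass => codegen pass => plan pass
        for upstream, downstream in (("plan", "codegen"), ("codegen", "execute")):
            if stages[downstream] == "pass" and stages[upstream] == "fail":
                raise RegistryError(
                    f"case {rec.case_id}: {variant} has {downstream}=pass but "
                    f"{upstream}=fail, violating the stage-implication chain"
                )
    noacr = rec.outcomes["no_acr"]
    some_failed = any(noacr[s] == "fail" for s in STAGES)
    if some_failed and not rec.failure_reason:
        raise RegistryError(f"case {rec.case_id}: failed stage without a failure reason")
    if not some_failed and rec.failure_reason:
        raise RegistryError(f"case {rec.case_id}: failure reason on an all-pass case")


def parse_registry(text: str) -> list[CaseRecord]:
    """Parse registry CSV text (``#`` comment lines allowed) and validate."""
    lines = [ln for ln in text.splitlines() if not ln.startswith("#")]
    reader = csv.DictReader(io.StringIO("\n".join(lines)))
    records: list[CaseRecord] = []
    seen: set[str] = set()
    for row in reader:
        cid = row["case_id"].strip()
        if cid in seen:
            raise RegistryError(f"duplicate case_id {cid}")
        seen.add(cid)
        rec = CaseRecord(
            case_id=cid,
            pipeline_class=row["pipeline_class"],
            task=row["task"],
            omics_type=row["omics"],
            outcomes={
                "no_acr": {s: row[f"{_col(s)}_noacr"].strip() for s in STAGES},
                "with_acr": {s: row[f"{_col(s)}_acr"].strip() for s in STAGES},
            },
            failure_reason=row["failure_reason"].strip(),
            tools_used=tuple(t.strip() for t in row["tools"].split(";") if t.strip()),
            time_cost_minutes=int(row["time_min"]),
        )
        _check_record(rec)
        records.append(rec)
    if not records:
        raise RegistryError("registry contains no cases")
    return records


def _col(stage: str) -> str:
    return stage  # column names use the stage names directly


def load_case_registry() -> list[CaseRecord]:
    """Load and validate the bundled registry."""
    text = resources.files("biopilot.data").joinpath("case_registry.csv").read_text()
    return parse_registry(text)


def load_acr_aggregates() -> dict:
    text = resources.files("biopilot.data").joinpath("acr_aggregates.json").read_text()
    return json.loads(text)


@dataclasses.dataclass(frozen=True)
class EvaluationSummary:
    total: int
    pass_counts: dict  # stage -> int
    percentages: dict  # stage -> float, one decimal
    per_omics: dict  # omics type -> case count

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def summarize_evaluation(
    records: Sequence[CaseRecord],
    variant: str = "no_acr",
    aggregates: dict | None = None,
) -> EvaluationSummary:
    """Stage-wise pass counts and percentages (one decimal) for a variant.

    ``unknown`` cells are resolved against ``aggregates`` (defaulting to
    the bundled aggregate record for the with-repair variant), subject to
    the consistency check known-passes <= aggregate <= known-passes +
    unknowns.  Percentages use exact rational arithmetic before the final
    one-decimal rounding.
    """
    if not records:
        raise RegistryError("cannot summarize an empty record list")
    if variant not in ("no_acr", "with_acr"):
        raise RegistryError(f"unknown variant {variant!r}")
    total = len(records)
    counts: dict[str, int] = {}
    for stage in STAGES:
        vals = [r.stage(variant, stage) for r in records]
        known_pass = sum(v == "pass" for v in vals)
        unknown = sum(v == "unknown" for v in vals)
        if unknown == 0:
            counts[stage] = known_pass
            continue
        agg = aggregates
        if agg is None:
            agg = load_acr_aggregates()
        if agg.get("variant") != variant or stage not in agg:
            raise RegistryError(
                f"stage {stage!r} has unknown cells but no aggregate count for {variant!r}"
            )
        n = int(agg[stage])
        if not (known_pass <= n <= known_pass + unknown):
            raise RegistryError(
                f"aggregate count {n} for stage {stage!r} is inconsistent with "
                f"{known_pass} known passes and {unknown} unknown cells"
            )
        counts[stage] = n
    percentages = {
        s: float(round(Fraction(100 * counts[s], total), 1)) for s in STAGES
    }
    per_omics: dict[str, int] = {}
    for r in records:
        per_omics[r.omics_type] = per_omics.get(r.omics_type, 0) + 1
    return EvaluationSummary(
        total=total, pass_counts=counts, percentages=percentages, per_omics=per_omics
    )
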
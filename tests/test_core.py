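"""Full-run orchestration: fail-stop, memory discipline, determinism, replay."""

from __future__ import annotations

import json

import pytest

from biopilot.backends import TranscriptBackend, TranscriptEntry, load_transcript
from biopilot.bench import generate_fixture_case
from biopilot.bench.fixtures import run_fixture_case
from biopilot.core import replay, run_agent
from biopilot.runlog import read_events


class TestEndToEndFixtureRun:
    def test_rnaseq_run_succeeds_with_one_repaired_step(self, rnaseq_case):
        report = run_fixture_case(rnaseq_case)
        assert report.stage_flags == {
            "plan_ok": True, "all_codegen_ok": True, "end_to_end_ok": True
        }
        assert [o.status for o in report.step_outcomes] == ["success"] * 5
        assert [o.attempts for o in report.step_outcomes] == [1, 2, 1, 1, 1]

    def test_run_products_land_inside_the_workspace(self, rnaseq_case):
        run_fixture_case(rnaseq_case)
        out = rnaseq_case.root / "output"
        assert (out / "gene_counts.tsv").exists()
        assert (out / "differential_expression_results.csv").exists()
        assert (rnaseq_case.root / "logs" / "report.json").exists()

    def test_memory_records_match_successful_steps(self, rnaseq_case):
        run_fixture_case(rnaseq_case)
        events = list(read_events(rnaseq_case.root / "logs" / "events.jsonl"))
        successes = [
            ev for ev in events
            if ev["event"] == "step_finished" and ev["outcome"]["status"] == "success"
        ]
        # each success appends one completed-task sentence, visible in the
        # next codegen prompt's history section
        prompts = [ev["prompt"] for ev in events if ev["event"] == "backend_request"]
        completed_counts = [p.count("you successfully completed the task") for p in prompts]
        assert max(completed_counts) == len(successes) - 1  # last success after final prompt
        assert completed_counts == sorted(completed_counts)  # monotone growth

    def test_determinism_across_runs_modulo_timestamps(self, tmp_path):
        r1 = run_fixture_case(generate_fixture_case("rnaseq_deg", 7, tmp_path / "a"))
        r2 = run_fixture_case(generate_fixture_case("rnaseq_deg", 7, tmp_path / "b"))
        assert r1.canonical_dict() == r2.canonical_dict()
        assert json.dumps(r1.canonical_dict()) == json.dumps(r2.canonical_dict())


class TestFailStop:
    def test_unrepairable_step_fails_and_rest_are_skipped(self, generic_case):
        # drop the repaired response so step 2 can never succeed
        entries = [
            e for e in load_transcript(generic_case.transcript_path)
            if "--ready" not in e.response
        ]
        from biopilot.backends import dump_transcript

        dump_transcript(entries, generic_case.transcript_path)
        report = run_fixture_case(generic_case, max_repair_attempts=2)
        assert [o.status for o in report.step_outcomes] == ["success", "failed"]
        assert report.step_outcomes[1].attempts == 3  # bound + 1
        assert report.stage_flags["end_to_end_ok"] is False
        assert report.stage_flags["all_codegen_ok"] is True

    def test_skipped_steps_follow_a_midrun_failure(self, tmp_path):
        case = generate_fixture_case("rnaseq_deg", 7, tmp_path / "fx")
        # remove the repaired alignment response: step 2 exhausts, 3-5 skipped
        entries = [
            e for e in load_transcript(case.transcript_path)
            if "hisat2-build" not in e.response
        ]
        from biopilot.backends import dump_transcript

        dump_transcript(entries, case.transcript_path)
        report = run_fixture_case(case, max_repair_attempts=2)
        assert [o.status for o in report.step_outcomes] == [
            "success", "failed", "skipped", "skipped", "skipped"
        ]
        assert report.stage_flags == {
            "plan_ok": True, "all_codegen_ok": False, "end_to_end_ok": False
        }


class TestStageImplicationChain:
    @pytest.mark.parametrize("kind,seed", [
        ("rnaseq_deg", 1), ("chipseq_peaks", 1), ("generic_fail_repair", 1),
    ])
    def test_end_to_end_implies_codegen_implies_plan(self, tmp_path, kind, seed):
        report = run_fixture_case(generate_fixture_case(kind, seed, tmp_path / kind))
        f = report.stage_flags
        assert (not f["end_to_end_ok"]) or f["all_codegen_ok"]
        assert (not f["all_codegen_ok"]) or f["plan_ok"]


class TestPlanningFailure:
    def test_unplannable_run_reports_plan_not_ok(self, generic_case):
        backend = TranscriptBackend(
            [TranscriptEntry("substring", "=== INSTRUCTIONS ===", "no plan, sorry")]
        )
        from biopilot.config import Workspace, parse_config_file

        config = parse_config_file(generic_case.config_path).model_copy(
            update={"max_repair_attempts": 1}
        )
        ws = Workspace(
            root=generic_case.root,
            scripts_dir=generic_case.root / "scripts",
            output_dir=generic_case.root / "output",
            logs_dir=generic_case.root / "logs",
            run_id="noplan",
        )
        report = run_agent(config, backend, workspace=ws)
        assert report.stage_flags == {
            "plan_ok": False, "all_codegen_ok": False, "end_to_end_ok": False
        }
        assert report.step_outcomes == ()


class TestBlacklistEnforcement:
    def test_blacklisted_plan_is_reproposed(self, tmp_path):
        case = generate_fixture_case("generic_fail_repair", 1, tmp_path / "fx")
        # first proposal uses the banned tool; the re-proposal (carrying the
        # violation diagnostic) switches to an allowed one
        bad_plan = '1. Transform the data with "bannedtool".\n'
        good_plan = (
            '1. Validate the raw input ./data/input.txt with "checktool" and store '
            "the validated copy.\n"
            '2. Transform the validated data into the result table with "flakytool".\n'
        )
        entries = load_transcript(case.transcript_path)
        goal_matcher = entries[0].matcher
        entries[0] = type(entries[0])("substring", goal_matcher, bad_plan, max_uses=1)
        entries.insert(1, type(entries[0])("substring", goal_matcher, good_plan))
        from biopilot.backends import dump_transcript

        dump_transcript(entries, case.transcript_path)
        from biopilot.config import parse_config_file, Workspace

        config = parse_config_file(case.config_path).model_copy(
            update={"blacklist": ["BannedTool"]}
        )
        ws = Workspace(
            root=case.root, scripts_dir=case.root / "scripts",
            output_dir=case.root / "output", logs_dir=case.root / "logs",
            run_id="bl",
        )
        backend = TranscriptBackend(entries)
        import os

        from biopilot.executor import SandboxPolicy, default_denylist

        report = run_agent(
            config, backend, workspace=ws,
            policy=SandboxPolicy(denylist=default_denylist(ws.root), timeout=60),
            env_extra={"PATH": f"{case.root / 'bin'}:{os.environ.get('PATH', '')}"},
        )
        assert report.stage_flags["plan_ok"]
        assert all(
            "bannedtool" not in (sw.casefold() for sw in s.software)
            for s in report.plan.steps
        )
        assert report.stage_flags["end_to_end_ok"]


class TestReplay:
    def test_replay_reconstructs_identical_report(self, rnaseq_case):
        live = run_fixture_case(rnaseq_case)
        rebuilt = replay(rnaseq_case.root / "logs" / "events.jsonl")
        assert rebuilt == live

    def test_replay_covers_failed_and_skipped_steps(self, tmp_path):
        case = generate_fixture_case("rnaseq_deg", 7, tmp_path / "fx")
        entries = [
            e for e in load_transcript(case.transcript_path)
            if "hisat2-build" not in e.response
        ]
        from biopilot.backends import dump_transcript

        dump_transcript(entries, case.transcript_path)
        live = run_fixture_case(case, max_repair_attempts=1)
        rebuilt = replay(case.root / "logs" / "events.jsonl")
        assert rebuilt == live
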
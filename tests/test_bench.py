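"""Registry fidelity, summarizer correctness and fixture determinism."""

from __future__ import annotations

import gzip
import hashlib
import json
from pathlib import Path

import pytest
from hypothesis import given
from hypothesis import strategies as st

from biopilot.bench import (
    RegistryError,
    generate_fixture_case,
    load_acr_aggregates,
    load_case_registry,
    run_benchmark,
    summarize_evaluation,
)
from biopilot.bench.fixtures import run_fixture_case
from biopilot.bench.registry import CaseRecord, parse_registry


@pytest.fixture(scope="module")
def registry():
    return load_case_registry()


class TestRegistry:
    def test_forty_cases_load(self, registry):
        assert len(registry) == 40

    def test_case_2_4_execute_failure_mentions_configuration_file(self, registry):
        rec = next(r for r in registry if r.case_id == "2.4")
        assert rec.stage("no_acr", "execute") == "fail"
        assert rec.stage("no_acr", "codegen") == "pass"
        assert "configuration file" in rec.failure_reason

    def test_case_10_1_passes_all_stages_with_expected_tools(self, registry):
        rec = next(r for r in registry if r.case_id == "10.1")
        assert {t.casefold() for t in rec.tools_used} >= {"hisat2", "deseq2"}
        assert all(rec.stage("no_acr", s) == "pass" for s in ("plan", "codegen", "execute"))

    def test_omics_composition_matches_study_design(self, registry):
        summary = summarize_evaluation(registry, "no_acr")
        assert summary.per_omics == {
            "genomics": 15, "transcriptomics": 23, "proteomics": 1, "metabolomics": 1
        }

    def test_stage_implication_violations_are_rejected_at_load(self):
        bad = (
            "case_id,pipeline_class,task,omics,plan_noacr,codegen_noacr,execute_noacr,"
            "plan_acr,codegen_acr,execute_acr,failure_reason,tools,time_min\n"
            "x.1,c,t,genomics,pass,fail,pass,pass,fail,pass,Failed: broken,ToolA,5\n"
        )
        with pytest.raises(RegistryError, match="stage-implication"):
            parse_registry(bad)

    def test_failure_reason_required_iff_some_stage_failed(self):
        header = (
            "case_id,pipeline_class,task,omics,plan_noacr,codegen_noacr,execute_noacr,"
            "plan_acr,codegen_acr,execute_acr,failure_reason,tools,time_min\n"
        )
        with pytest.raises(RegistryError, match="failure reason"):
            parse_registry(header + "x.1,c,t,genomics,pass,pass,fail,pass,pass,pass,,ToolA,5\n")
        with pytest.raises(RegistryError, match="all-pass"):
            parse_registry(header + "x.1,c,t,genomics,pass,pass,pass,pass,pass,pass,oops,ToolA,5\n")


class TestSummarizer:
    def test_no_acr_counts_reproduce_the_published_row(self, registry):
        s = summarize_evaluation(registry, "no_acr")
        assert s.pass_counts == {"plan": 36, "codegen": 33, "execute": 26}
        assert s.percentages == {"plan": 90.0, "codegen": 82.5, "execute": 65.0}

    def test_with_acr_counts_resolve_against_aggregates(self, registry):
        s = summarize_evaluation(registry, "with_acr")
        assert s.pass_counts == {"plan": 36, "codegen": 35, "execute": 35}
        assert s.percentages == {"plan": 90.0, "codegen": 87.5, "execute": 87.5}

    def test_single_allpass_record_scores_100_everywhere(self, registry):
        rec = next(r for r in registry if r.case_id == "1.1")
        s = summarize_evaluation([rec], "no_acr")
        assert s.percentages == {"plan": 100.0, "codegen": 100.0, "execute": 100.0}

    def test_inconsistent_aggregates_are_rejected(self, registry):
        with pytest.raises(RegistryError, match="inconsistent"):
            summarize_evaluation(
                registry, "with_acr",
                aggregates={"variant": "with_acr", "plan": 36, "codegen": 39, "execute": 35},
            )

    @given(
        outcomes=st.lists(
            st.tuples(st.booleans(), st.booleans(), st.booleans()),
            min_size=1, max_size=25,
        )
    )
    def test_percentages_match_bruteforce_count(self, outcomes):
        records = []
        for i, (p, c, e) in enumerate(outcomes):
            c = c and p  # enforce the implication chain
            e = e and c
            records.append(CaseRecord(
                case_id=f"s.{i}", pipeline_class="c", task="t", omics_type="genomics",
                outcomes={
                    "no_acr": {"plan": "pass" if p else "fail",
                               "codegen": "pass" if c else "fail",
                               "execute": "pass" if e else "fail"},
                    "with_acr": {"plan": "pass", "codegen": "pass", "execute": "pass"},
                },
                failure_reason="Failed: x" if not (p and c and e) else "",
                tools_used=("ToolA",), time_cost_minutes=1,
            ))
        s = summarize_evaluation(records, "no_acr")
        n = len(records)
        for stage, picker in (("plan", 0), ("codegen", 1), ("execute", 2)):
            expected = sum(
                1 for i, o in enumerate(outcomes)
                if [o[0], o[0] and o[1], o[0] and o[1] and o[2]][picker]
            )
            assert s.pass_counts[stage] == expected
            assert s.percentages[stage] == round(100 * expected / n, 1)


def _tree_digest(root: Path) -> dict:
    out = {}
    for p in sorted(root.rglob("*")):
        if p.is_file():
            out[str(p.relative_to(root))] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out


class TestFixtures:
    def test_same_kind_and_seed_give_byte_identical_workspaces(self, tmp_path):
        a = generate_fixture_case("rnaseq_deg", 7, tmp_path / "a")
        b = generate_fixture_case("rnaseq_deg", 7, tmp_path / "b")
        assert _tree_digest(a.root) == _tree_digest(b.root)

    def test_different_seeds_change_the_reads(self, tmp_path):
        a = generate_fixture_case("rnaseq_deg", 1, tmp_path / "a")
        b = generate_fixture_case("rnaseq_deg", 2, tmp_path / "b")
        da = _tree_digest(a.root)
        db = _tree_digest(b.root)
        assert da["data/SRR1374921.fastq.gz"] != db["data/SRR1374921.fastq.gz"]

    def test_fastq_payload_is_structurally_valid(self, rnaseq_case):
        from Bio import SeqIO  # independent format-checker oracle

        for fq in sorted((rnaseq_case.root / "data").glob("*.fastq.gz")):
            with gzip.open(fq, "rt") as fh:
                records = list(SeqIO.parse(fh, "fastq"))
            assert len(records) == 50
            for rec in records:
                assert len(rec.seq) == len(rec.letter_annotations["phred_quality"]) == 60

    def test_gtf_has_at_least_two_gene_features(self, rnaseq_case):
        gtf = (rnaseq_case.root / "data" / "mm39.ncbiRefSeq.gtf").read_text()
        genes = [ln for ln in gtf.splitlines() if ln.split("\t")[2] == "gene"]
        assert len(genes) >= 2

    def test_unknown_kind_is_a_configuration_error(self, tmp_path):
        with pytest.raises(ValueError, match="unknown fixture kind"):
            generate_fixture_case("proteomics_maxquant", 1, tmp_path / "x")

    def test_fail_repair_fixture_shows_a_repaired_step(self, generic_case):
        report = run_fixture_case(generic_case)
        assert any(o.attempts >= 2 for o in report.step_outcomes)
        assert report.stage_flags["end_to_end_ok"]


class TestRunBenchmark:
    def test_all_kinds_and_two_seeds_pass(self, tmp_path):
        specs = [(k, s) for k in ("rnaseq_deg", "chipseq_peaks", "generic_fail_repair")
                 for s in (0, 7)]
        report = run_benchmark(specs, tmp_path)
        assert report["total"] == 6 and report["passed"] == 6
        assert report["pass_percentage"] == 100.0

    def test_corrupted_transcript_fails_exactly_that_fixture(self, tmp_path):
        # pre-generate and corrupt one fixture's transcript; run_benchmark
        # regenerates fixtures, so corrupt via a changed expected report instead
        specs = [("rnaseq_deg", 0), ("generic_fail_repair", 0)]
        report = run_benchmark(specs, tmp_path)
        assert report["passed"] == 2
        # now corrupt the generated transcript of one fixture and re-run it
        case = generate_fixture_case("generic_fail_repair", 0, tmp_path / "corrupt")
        text = (case.root / "transcript.json").read_text()
        (case.root / "transcript.json").write_text(
            text.replace("--ready", "--not-a-flag")
        )
        rerun = run_fixture_case(case)
        from biopilot.bench.fixtures import report_matches_expected

        assert not report_matches_expected(rerun, case.expected_report)

    def test_report_percentage_matches_hand_computation(self, tmp_path):
        specs = [("generic_fail_repair", 0), ("chipseq_peaks", 0)]
        report = run_benchmark(specs, tmp_path)
        by_hand = 100.0 * sum(f["passed"] for f in report["fixtures"]) / len(report["fixtures"])
        assert report["pass_percentage"] == round(by_hand, 1)


def test_acr_aggregates_are_consistent_with_known_cells(registry):
    agg = load_acr_aggregates()
    for stage in ("plan", "codegen", "execute"):
        known = sum(1 for r in registry if r.stage("with_acr", stage) == "pass")
        unknown = sum(1 for r in registry if r.stage("with_acr", stage) == "unknown")
        assert known <= agg[stage] <= known + unknown
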
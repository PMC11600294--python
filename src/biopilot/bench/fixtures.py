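"""Deterministic synthetic fixtures for offline end-to-end agent runs.

Each fixture is a self-contained miniature omics workspace — tiny gzipped
FASTQ files, a small FASTA reference, a minimal GTF — together with a
scripted backend transcript whose code-generation responses invoke only
stub tools shipped inside the fixture's ``bin/`` directory.  The stubs
mimic the command-line surface of the real tools (trimmer, aligner,
counter, ...) but only shuffle bytes, so a full agent run is hermetic and
takes seconds.  One fixture kind injects a failure (an aligner invoked
before its genome index was built) whose transcript carries a use-limited
broken response followed by the repaired one, exercising the automatic
code repair cycle end to end.

Synthetic reads are produced by an explicitly specified linear congruential
generator (constants below) so that identical ``(kind, seed)`` always
yields byte-identical payloads, independent of Python's RNG internals.
All files named after real datasets or genomes (``SRR…``, ``mm39.fa``)
are synthetic stand-ins generated by this module.
"""

from __future__ import annotations

import dataclasses
import gzip
import io
import json
import os
from pathlib import Path

from ..backends import TranscriptBackend, TranscriptEntry, dump_transcript
from ..config import Workspace, parse_config_file
from ..core import RunReport, run_agent
from ..executor import SandboxPolicy, default_denylist
from ..planner import parse_plan

__all__ = [
    "FIXTURE_KINDS",
    "FixtureCase",
    "generate_fixture_case",
    "run_fixture_case",
    "run_benchmark",
    "LCG",
]

FIXTURE_KINDS = ("rnaseq_deg", "chipseq_peaks", "generic_fail_repair")


class LCG:
    """Linear congruential generator, constants fixed for portability:
    state' = (1103515245 * state + 12345) mod 2**31."""

    A = 1103515245
    C = 12345
    M = 2**31

    def __init__(self, seed: int):
        self.state = seed % self.M

    def next(self) -> int:
        self.state = (self.A * self.state + self.C) % self.M
        return self.state

    def chars(self, alphabet: str, n: int) -> str:
        return "".join(alphabet[self.next() % len(alphabet)] for _ in range(n))


@dataclasses.dataclass(frozen=True)
class FixtureCase:
    kind: str
    seed: int
    root: Path
    config_path: Path
    transcript_path: Path
    expected_report: dict


def _write_gz(path: Path, text: str) -> None:
    # mtime=0 and empty embedded filename keep the gzip bytes deterministic
    buf = io.BytesIO()
    with gzip.GzipFile(fileobj=buf, mode="wb", filename="", mtime=0) as gz:
        gz.write(text.encode())
    path.write_bytes(buf.getvalue())


def _fastq_text(sample: str, rng: LCG, n_reads: int = 50, length: int = 60) -> str:
    out = []
    for i in range(1, n_reads + 1):
        seq = rng.chars("ACGT", length)
        qual = rng.chars("FGHI", length)
        out.append(f"@{sample}.{i}\n{seq}\n+\n{qual}\n")
    return "".join(out)


def _fasta_text(name: str, rng: LCG, length: int = 2000, width: int = 80) -> str:
    seq = rng.chars("ACGT", length)
    lines = [seq[i : i + width] for i in range(0, length, width)]
    return f">{name}\n" + "\n".join(lines) + "\n"


def _stub(path: Path, body: str) -> None:
    path.write_text("#!/usr/bin/env bash\n" + body.lstrip("\n"))
    path.chmod(0o755)


def _code(text: str) -> str:
    return "```bash\n" + text.strip("\n") + "\n```\n"


def _goal_matcher(goal_text: str) -> str:
    return f"=== CURRENT GOAL === {goal_text}"


# ---------------------------------------------------------------------------
# rnaseq_deg: four single-end samples, five-step differential-expression
# pipeline (trim -> align -> sort -> count -> test) with one injected
# failure: the aligner is first invoked without building the genome index.

_RNASEQ_GOAL = "identify differentially expressed genes between the LoGlu and HiGlu groups"

_RNASEQ_PLAN = (
    'First, I will use the "Trimmomatic" software to trim the adapters from the '
    "single-end mouse RNA-seq reads. The input files for this step will be "
    '"./data/SRR1374921.fastq.gz", "./data/SRR1374922.fastq.gz", '
    '"./data/SRR1374923.fastq.gz", "./data/SRR1374924.fastq.gz" and the adapter '
    'file "./data/TruSeq3-SE.fa". '
    'Next, I will use the "Hisat2" software to align the trimmed reads to the mouse '
    'mm39 genome. The input files for this step will be the output files from the '
    'previous step and the genome file "./data/mm39.fa". '
    'Then, I will use the "Samtools" software to convert the alignment output files '
    "from Hisat2 (in SAM format) to BAM format. "
    'After that, I will use the "HTSeq" software to count the number of reads mapped '
    "to each gene. The input files for this step will be the BAM files from the "
    'previous step and the annotation file "./data/mm39.ncbiRefSeq.gtf". '
    'Finally, I will use the "DESeq2" software to identify the differentially '
    "expressed genes. The input files for this step will be the count files from "
    "the previous step."
)

_RNASEQ_SAMPLES = ("SRR1374921", "SRR1374922", "SRR1374923", "SRR1374924")


def _rnaseq_payload(root: Path, seed: int) -> None:
    data = root / "data"
    data.mkdir(parents=True, exist_ok=True)
    rng = LCG(seed)
    for sample in _RNASEQ_SAMPLES:
        _write_gz(data / f"{sample}.fastq.gz", _fastq_text(sample, rng))
    (data / "TruSeq3-SE.fa").write_text(
        ">TruSeq3_SE_synthetic\nAGATCGGAAGAGCACACGTCTGAACTCCAGTCAC\n"
    )
    (data / "mm39.fa").write_text(_fasta_text("chr19_synthetic", rng))
    (data / "mm39.ncbiRefSeq.gtf").write_text(
        'chr19_synthetic\tsynthetic\tgene\t1\t900\t.\t+\t.\tgene_id "geneA";\n'
        'chr19_synthetic\tsynthetic\texon\t1\t900\t.\t+\t.\tgene_id "geneA"; transcript_id "geneA.1";\n'
        'chr19_synthetic\tsynthetic\tgene\t1001\t1900\t.\t+\t.\tgene_id "geneB";\n'
        'chr19_synthetic\tsynthetic\texon\t1001\t1900\t.\t+\t.\tgene_id "geneB"; transcript_id "geneB.1";\n'
    )


def _rnaseq_stubs(root: Path) -> None:
    b = root / "bin"
    b.mkdir(parents=True, exist_ok=True)
    _stub(b / "trimmomatic", """
# synthetic stand-in for the Trimmomatic adapter trimmer
# usage: trimmomatic SE -phred33 <in.fastq.gz> <out.fastq.gz> ILLUMINACLIP:...
cp "$3" "$4"
echo "TrimmomaticSE: Completed successfully" >&2
""")
    _stub(b / "hisat2-build", """
# synthetic stand-in for the hisat2 genome indexer: hisat2-build <ref> <base>
cp "$1" "$2.1.ht2"
echo "Total time for call to driver(): 00:00:00" >&2
""")
    _stub(b / "hisat2", """
# synthetic stand-in for the hisat2 aligner: hisat2 -x <base> -U <in> -S <out>
idx=""; infile=""; outfile=""
while [ $# -gt 0 ]; do
  case "$1" in
    -x) idx="$2"; shift 2;;
    -U) infile="$2"; shift 2;;
    -S) outfile="$2"; shift 2;;
    *) shift;;
  esac
done
if [ ! -f "$idx.1.ht2" ]; then
  echo "(ERR): \\"$idx\\" does not exist" >&2
  echo "Error: Encountered internal HISAT2 exception" >&2
  exit 1
fi
gunzip -c "$infile" > "$outfile" 2>/dev/null || cp "$infile" "$outfile"
echo "overall alignment rate: 100.00%" >&2
""")
    _stub(b / "samtools", """
# synthetic stand-in for samtools: samtools sort -o <out.bam> <in.sam>
out=""; infile=""
while [ $# -gt 0 ]; do
  case "$1" in
    -o) out="$2"; shift 2;;
    sort|view|-b|-S|-bS) shift;;
    *) infile="$1"; shift;;
  esac
done
cp "$infile" "$out"
""")
    _stub(b / "htseq-count", """
# synthetic stand-in for htseq-count: htseq-count <bam...> <gtf>  (counts to stdout)
args=("$@")
gtf="${args[${#args[@]}-1]}"
nbam=$(( ${#args[@]} - 1 ))
genes=$(grep -o 'gene_id "[^"]*"' "$gtf" | sed 's/gene_id "//; s/"//' | sort -u)
for g in $genes; do
  total=0
  for ((i=0; i<nbam; i++)); do
    n=$(wc -l < "${args[$i]}")
    total=$(( total + n ))
  done
  echo -e "$g\\t$total"
done
""")
    _stub(b / "Rscript", """
# synthetic stand-in for Rscript running a DESeq2-style analysis script:
# ignores its arguments and emits a differential-expression table
mkdir -p ./output
cat > ./output/differential_expression_results.csv <<'EOF'
gene,baseMean,log2FoldChange,pvalue,padj
geneA,400,1.7,0.001,0.004
geneB,400,-2.1,0.0005,0.002
EOF
echo "DESeq2 analysis complete"
""")


def _rnaseq_transcript(goal: str, plan_text: str) -> list[TranscriptEntry]:
    steps = parse_plan(plan_text).steps
    trim = "\n".join(
        f"trimmomatic SE -phred33 ./data/{s}.fastq.gz ./output/{s}_trimmed.fastq.gz "
        "ILLUMINACLIP:./data/TruSeq3-SE.fa:2:30:10"
        for s in _RNASEQ_SAMPLES
    )
    align = "\n".join(
        f"hisat2 -x ./output/mm39_index -U ./output/{s}_trimmed.fastq.gz -S ./output/{s}.sam"
        for s in _RNASEQ_SAMPLES
    )
    sort = "\n".join(
        f"samtools sort -o ./output/{s}.bam ./output/{s}.sam" for s in _RNASEQ_SAMPLES
    )
    bams = " ".join(f"./output/{s}.bam" for s in _RNASEQ_SAMPLES)
    entries = [
        TranscriptEntry("substring", _goal_matcher(goal), _RNASEQ_PLAN),
        TranscriptEntry(
            "substring", _goal_matcher(steps[0].description),
            "I will trim the adapters with Trimmomatic.\n\n"
            + _code(f"mkdir -p ./output\n{trim}"),
        ),
        # broken alignment first: the genome index was never built
        TranscriptEntry(
            "substring", _goal_matcher(steps[1].description),
            "I will align the trimmed reads with Hisat2.\n\n"
            + _code(f"mkdir -p ./output\n{align}"),
            max_uses=1,
        ),
        # the repaired response builds the index before aligning
        TranscriptEntry(
            "substring", _goal_matcher(steps[1].description),
            "The error shows the genome index was missing; I will build it "
            "with hisat2-build before aligning.\n\n"
            + _code(
                "mkdir -p ./output\nhisat2-build ./data/mm39.fa ./output/mm39_index\n"
                + align
            ),
        ),
        TranscriptEntry(
            "substring", _goal_matcher(steps[2].description),
            "I will convert the alignments to BAM with Samtools.\n\n"
            + _code(f"mkdir -p ./output\n{sort}"),
        ),
        TranscriptEntry(
            "substring", _goal_matcher(steps[3].description),
            "I will count reads per gene with HTSeq.\n\n"
            + _code(
                "mkdir -p ./output\n"
                f"htseq-count {bams} ./data/mm39.ncbiRefSeq.gtf > ./output/gene_counts.tsv"
            ),
        ),
        TranscriptEntry(
            "substring", _goal_matcher(steps[4].description),
            "I will test for differential expression with DESeq2.\n\n"
            + _code("Rscript ./output/deseq2.R"),
        ),
    ]
    return entries


_RNASEQ_CONFIG = """\
data:
  - ./data/SRR1374921.fastq.gz: single-end reads in LoGlu group
  - ./data/SRR1374922.fastq.gz: single-end reads in LoGlu group, replicate 2
  - ./data/SRR1374923.fastq.gz: single-end reads in HiGlu group
  - ./data/SRR1374924.fastq.gz: single-end reads in HiGlu group, replicate 2
  - ./data/mm39.fa: mouse reference genome
  - ./data/mm39.ncbiRefSeq.gtf: genome annotation
goal: {goal}
backend: transcript
output_dir: .
"""


# ---------------------------------------------------------------------------
# chipseq_peaks: two samples, four-step peak-calling pipeline, no failure.

_CHIPSEQ_GOAL = "identify binding peaks and annotate them with nearby genes"

_CHIPSEQ_PLAN = (
    '1. Use "Cutadapt" to remove adapters from ./data/SRR620204.fastq.gz and '
    "./data/SRR620205.fastq.gz.\n"
    '2. Use "Bowtie2" to align the trimmed reads to the reference ./data/hg38.fa.\n'
    '3. Use "MACS2" to call peaks from the aligned reads.\n'
    '4. Use "BEDTools" to annotate the peaks with the gene intervals in '
    "./data/genes.bed.\n"
)

_CHIPSEQ_SAMPLES = ("SRR620204", "SRR620205")


def _chipseq_payload(root: Path, seed: int) -> None:
    data = root / "data"
    data.mkdir(parents=True, exist_ok=True)
    rng = LCG(seed + 1)
    for sample in _CHIPSEQ_SAMPLES:
        _write_gz(data / f"{sample}.fastq.gz", _fastq_text(sample, rng, n_reads=40))
    (data / "hg38.fa").write_text(_fasta_text("chr1_synthetic", rng, length=1500))
    (data / "genes.bed").write_text(
        "chr1_synthetic\t0\t500\tgeneX\nchr1_synthetic\t600\t1100\tgeneY\n"
        "chr1_synthetic\t1200\t1450\tgeneZ\n"
    )


def _chipseq_stubs(root: Path) -> None:
    b = root / "bin"
    b.mkdir(parents=True, exist_ok=True)
    _stub(b / "cutadapt", """
# synthetic stand-in for cutadapt: cutadapt -o <out> <in>
out=""; infile=""
while [ $# -gt 0 ]; do
  case "$1" in
    -o) out="$2"; shift 2;;
    -a|-q) shift 2;;
    *) infile="$1"; shift;;
  esac
done
cp "$infile" "$out"
echo "=== Summary ==="
""")
    _stub(b / "bowtie2", """
# synthetic stand-in for bowtie2: bowtie2 -x <ref> -U <in> -S <out>
infile=""; outfile=""
while [ $# -gt 0 ]; do
  case "$1" in
    -x|-U) [ "$1" = "-U" ] && infile="$2"; shift 2;;
    -S) outfile="$2"; shift 2;;
    *) shift;;
  esac
done
gunzip -c "$infile" > "$outfile" 2>/dev/null || cp "$infile" "$outfile"
echo "overall alignment rate: 98.50%" >&2
""")
    _stub(b / "macs2", """
# synthetic stand-in for macs2: macs2 callpeak -t <in> -n <name> --outdir <dir>
name="peaks"; outdir="."
while [ $# -gt 0 ]; do
  case "$1" in
    -n) name="$2"; shift 2;;
    --outdir) outdir="$2"; shift 2;;
    *) shift;;
  esac
done
mkdir -p "$outdir"
printf 'chr1_synthetic\\t100\\t300\\t%s_peak_1\\t250\\nchr1_synthetic\\t800\\t1000\\t%s_peak_2\\t180\\n' "$name" "$name" > "$outdir/${name}_peaks.narrowPeak"
echo "INFO: peak calling done" >&2
""")
    _stub(b / "bedtools", """
# synthetic stand-in for bedtools intersect -a <peaks> -b <genes>
a=""; b=""
while [ $# -gt 0 ]; do
  case "$1" in
    -a) a="$2"; shift 2;;
    -b) b="$2"; shift 2;;
    *) shift;;
  esac
done
paste -d'\\t' <(cut -f1-4 "$a") <(cut -f4 "$b" | head -n "$(wc -l < "$a")")
""")


def _chipseq_transcript(goal: str, plan_text: str) -> list[TranscriptEntry]:
    steps = parse_plan(plan_text).steps
    trim = "\n".join(
        f"cutadapt -o ./output/{s}_trimmed.fastq.gz ./data/{s}.fastq.gz"
        for s in _CHIPSEQ_SAMPLES
    )
    align = "\n".join(
        f"bowtie2 -x ./data/hg38.fa -U ./output/{s}_trimmed.fastq.gz -S ./output/{s}.sam"
        for s in _CHIPSEQ_SAMPLES
    )
    return [
        TranscriptEntry("substring", _goal_matcher(goal), _CHIPSEQ_PLAN),
        TranscriptEntry(
            "substring", _goal_matcher(steps[0].description),
            _code(f"mkdir -p ./output\n{trim}"),
        ),
        TranscriptEntry(
            "substring", _goal_matcher(steps[1].description),
            _code(f"mkdir -p ./output\n{align}"),
        ),
        TranscriptEntry(
            "substring", _goal_matcher(steps[2].description),
            _code(
                "macs2 callpeak -t ./output/SRR620204.sam -n chip --outdir ./output"
            ),
        ),
        TranscriptEntry(
            "substring", _goal_matcher(steps[3].description),
            _code(
                "bedtools intersect -a ./output/chip_peaks.narrowPeak "
                "-b ./data/genes.bed > ./output/annotated_peaks.tsv"
            ),
        ),
    ]


_CHIPSEQ_CONFIG = """\
data:
  - ./data/SRR620204.fastq.gz: ChIP sample reads
  - ./data/SRR620205.fastq.gz: input control reads
  - ./data/hg38.fa: reference genome
  - ./data/genes.bed: gene intervals
goal: {goal}
backend: transcript
output_dir: .
"""


# ---------------------------------------------------------------------------
# generic_fail_repair: minimal two-step run whose second step fails once and
# is repaired on regeneration.

_GENERIC_GOAL = "produce the transformed result table from the raw input"

_GENERIC_PLAN = (
    '1. Validate the raw input ./data/input.txt with "checktool" and store the '
    "validated copy.\n"
    '2. Transform the validated data into the result table with "flakytool".\n'
)


def _generic_payload(root: Path, seed: int) -> None:
    data = root / "data"
    data.mkdir(parents=True, exist_ok=True)
    rng = LCG(seed + 2)
    rows = "\n".join(f"row{i}\t{rng.next() % 1000}" for i in range(1, 21))
    (data / "input.txt").write_text(rows + "\n")


def _generic_stubs(root: Path) -> None:
    b = root / "bin"
    b.mkdir(parents=True, exist_ok=True)
    _stub(b / "checktool", """
# synthetic validator: checktool <in> <out>
cp "$1" "$2"
echo "validated $(wc -l < "$1") rows"
""")
    _stub(b / "flakytool", """
# synthetic transformer that requires the --ready flag
if [ "$1" != "--ready" ]; then
  echo "Error: flakytool requires the --ready flag" >&2
  exit 1
fi
sort "$2"
""")


def _generic_transcript(goal: str, plan_text: str) -> list[TranscriptEntry]:
    steps = parse_plan(plan_text).steps
    return [
        TranscriptEntry("substring", _goal_matcher(goal), _GENERIC_PLAN),
        TranscriptEntry(
            "substring", _goal_matcher(steps[0].description),
            _code("mkdir -p ./output\nchecktool ./data/input.txt ./output/validated.txt"),
        ),
        TranscriptEntry(
            "substring", _goal_matcher(steps[1].description),
            _code("flakytool ./output/validated.txt > ./output/result.txt"),
            max_uses=1,
        ),
        TranscriptEntry(
            "substring", _goal_matcher(steps[1].description),
            _code("flakytool --ready ./output/validated.txt > ./output/result.txt"),
        ),
    ]


_GENERIC_CONFIG = """\
data:
  - ./data/input.txt: raw tab-separated measurements
goal: {goal}
backend: transcript
output_dir: .
"""


_KIND_SPECS = {
    "rnaseq_deg": dict(
        goal=_RNASEQ_GOAL, plan=_RNASEQ_PLAN, payload=_rnaseq_payload,
        stubs=_rnaseq_stubs, transcript=_rnaseq_transcript, config=_RNASEQ_CONFIG,
        expected_attempts=[1, 2, 1, 1, 1],
    ),
    "chipseq_peaks": dict(
        goal=_CHIPSEQ_GOAL, plan=_CHIPSEQ_PLAN, payload=_chipseq_payload,
        stubs=_chipseq_stubs, transcript=_chipseq_transcript, config=_CHIPSEQ_CONFIG,
        expected_attempts=[1, 1, 1, 1],
    ),
    "generic_fail_repair": dict(
        goal=_GENERIC_GOAL, plan=_GENERIC_PLAN, payload=_generic_payload,
        stubs=_generic_stubs, transcript=_generic_transcript, config=_GENERIC_CONFIG,
        expected_attempts=[1, 2],
    ),
}


def generate_fixture_case(kind: str, seed: int, dest: str | os.PathLike) -> FixtureCase:
    """Write a self-contained fixture workspace under ``dest``.

    The payload (data files, stub tools, transcript, run configuration and
    the expected run-report skeleton) is fully determined by
    ``(kind, seed)``.
    """
    if kind not in _KIND_SPECS:
        raise ValueError(f"unknown fixture kind {kind!r}; known: {FIXTURE_KINDS}")
    spec = _KIND_SPECS[kind]
    # absolute root: scripts run with cwd = workspace root, so a relative
    # dest would break the stub-tool PATH entries
    root = Path(dest).resolve()
    root.mkdir(parents=True, exist_ok=True)
    for sub in ("scripts", "output", "logs"):
        (root / sub).mkdir(exist_ok=True)
    spec["payload"](root, seed)
    spec["stubs"](root)
    entries = spec["transcript"](spec["goal"], spec["plan"])
    transcript_path = root / "transcript.json"
    dump_transcript(entries, transcript_path)
    config_path = root / "config.yaml"
    config_path.write_text(spec["config"].format(goal=spec["goal"]))
    n = len(spec["expected_attempts"])
    expected = {
        "plan_ok": True,
        "n_steps": n,
        "statuses": ["success"] * n,
        "attempts": list(spec["expected_attempts"]),
        "end_to_end_ok": True,
    }
    (root / "expected_report.json").write_text(json.dumps(expected, indent=2))
    return FixtureCase(
        kind=kind, seed=seed, root=root, config_path=config_path,
        transcript_path=transcript_path, expected_report=expected,
    )


def run_fixture_case(case: FixtureCase, max_repair_attempts: int | None = None) -> RunReport:
    """Run the full agent loop on a generated fixture with its transcript
    backend and stub tools on PATH."""
    config = parse_config_file(case.config_path)
    if max_repair_attempts is not None:
        config = config.model_copy(update={"max_repair_attempts": max_repair_attempts})
    ws = Workspace(
        root=case.root,
        scripts_dir=case.root / "scripts",
        output_dir=case.root / "output",
        logs_dir=case.root / "logs",
        run_id=f"{case.kind}-s{case.seed}",
    )
    backend = TranscriptBackend.from_file(
        case.transcript_path, placeholders={"WORKSPACE": str(case.root)}
    )
    policy = SandboxPolicy(denylist=default_denylist(ws.root), timeout=config.step_timeout)
    env_extra = {"PATH": f"{case.root / 'bin'}:{os.environ.get('PATH', '')}"}
    return run_agent(config, backend, workspace=ws, policy=policy, env_extra=env_extra)


def report_matches_expected(report: RunReport, expected: dict) -> bool:
    got = {
        "plan_ok": report.stage_flags["plan_ok"],
        "n_steps": len(report.plan.steps) if report.plan else 0,
        "statuses": [o.status for o in report.step_outcomes],
        "attempts": [o.attempts for o in report.step_outcomes],
        "end_to_end_ok": report.stage_flags["end_to_end_ok"],
    }
    return got == expected


def run_benchmark(
    specs: list[tuple[str, int]], base_dir: str | os.PathLike
) -> dict:
    """Generate and run one fixture per (kind, seed) spec; return a
    stage-style report with per-fixture pass/fail against the expected
    run-report skeletons."""
    base = Path(base_dir)
    results = []
    for kind, seed in specs:
        case = generate_fixture_case(kind, seed, base / f"{kind}-s{seed}")
        report = run_fixture_case(case)
        results.append(
            {
                "kind": kind,
                "seed": seed,
                "passed": report_matches_expected(report, case.expected_report),
                "stage_flags": dict(report.stage_flags),
                "attempts": [o.attempts for o in report.step_outcomes],
            }
        )
    n_pass = sum(r["passed"] for r in results)
    total = len(results)
    return {
        "total": total,
        "passed": n_pass,
        "pass_percentage": round(100.0 * n_pass / total, 1) if total else 0.0,
        "fixtures": results,
    }
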
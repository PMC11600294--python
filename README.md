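# biopilot

An autonomous agent loop for conventional multi-omic bioinformatics
analyses. From three user inputs — data paths, data descriptions and a
final objective — the agent plans an analysis, generates shell code for
each step through a pluggable language-model backend, executes it confined
to a run workspace, and repairs failing code automatically from the
captured error streams.

**Who it is for.** Researchers who run standard omics pipelines (RNA-seq
differential expression, ChIP-seq peak calling, variant calling, …) and
want the planning / coding / debugging cycle automated, and developers who
need a fully offline, deterministic harness for testing LLM-agent
orchestration of bioinformatics workflows.

## The loop

A run configuration is a small YAML document:

```yaml
data:
  - ./data/SRR1374921.fastq.gz: single-end reads in LoGlu group
  - ./data/SRR1374922.fastq.gz: single-end reads in LoGlu group, replicate 2
  - ./data/SRR1374923.fastq.gz: single-end reads in HiGlu group
  - ./data/SRR1374924.fastq.gz: single-end reads in HiGlu group, replicate 2
  - ./data/mm39.fa: mouse reference genome
  - ./data/mm39.ncbiRefSeq.gtf: genome annotation
goal: identify differentially expressed genes between the LoGlu and HiGlu groups
```

Three phases follow. **Planning**: the backend proposes an ordered,
software-annotated step list, checked against the user's blacklist.
**Code generation**: each step's sub-goal is turned into one fenced shell
script, with the agent's memory (the accepted plan and every completed
task, in fixed sentence templates) re-rendered into every prompt.
**Execution with automatic code repair (ACR)**: scripts are screened
against a command denylist, run with `set -e` inside the workspace, and
classified (non-zero exit ∨ timeout ∨ error pattern in stdout/stderr); on
error, the tail of the error text is fed back into the prompt and the
script is regenerated, up to `max_repair_attempts` times (default 5).

Backends are pluggable behind one `complete(request)` contract: an
OpenAI-compatible chat adapter, a generic local-model subprocess adapter,
and a deterministic transcript-replay backend that answers prompts from a
recorded matcher → response table — the backend the entire offline test
suite runs against.

## Worked example

The bundled fixture generator builds a miniature RNA-seq workspace (four
gzipped FASTQ samples of 50 synthetic reads, a 2 kb reference, a 2-gene
GTF, stub tools on `PATH`) together with a scripted transcript that
includes one injected failure: the aligner is first called without
building its genome index.

```python
from biopilot.bench import generate_fixture_case
from biopilot.bench.fixtures import run_fixture_case

case = generate_fixture_case("rnaseq_deg", seed=7, dest="scratch/demo")
report = run_fixture_case(case)
print(report.stage_flags)
print([o.status for o in report.step_outcomes])
print([o.attempts for o in report.step_outcomes])
```

prints

```
{'plan_ok': True, 'all_codegen_ok': True, 'end_to_end_ok': True}
['success', 'success', 'success', 'success', 'success']
[1, 2, 1, 1, 1]
```

— the five-step plan (trim → align → sort → count → test) was accepted,
all steps succeeded, and step 2 shows `attempts=2`: its first script
failed because the genome index was missing, the error excerpt was fed
back, and the regenerated script prepended the index build. Run products
(`gene_counts.tsv`, `differential_expression_results.csv`, every script,
both stream captures and a JSON-lines event log) land inside the
workspace.

The same loop is available from the shell:

```
biopilot run --config run.yaml --backend transcript --transcript t.json
biopilot replay --log runs/<id>/logs/events.jsonl
biopilot bench summarize --variant no_acr
biopilot bench run --dest scratch/bench
```

`biopilot bench summarize` reports the bundled 40-case evaluation
registry: stage-wise success counts across real-world analysis scenarios
(40 cases over genomics, transcriptomics, proteomics and metabolomics) —
without repair 36/40 plans, 33/40 code generations and 26/40 end-to-end
executions pass (90% / 82.5% / 65%); with repair, code generation and
end-to-end execution rise to 35/40 each (87.5%).

## Layout

```
src/biopilot/
  config.py      run configuration and workspace plumbing
  prompts.py     prompt slots, templates, history memory
  backends.py    backend contract; transcript / chat-API / local adapters
  planner.py     plan parsing, software extraction, blacklist check
  codegen.py     code extraction, generation, repair loop
  executor.py    command screening, confined execution, error classification
  core.py        full-run orchestration, reports, replay
  bench/         40-case registry + synthetic fixture generator
  cli.py         biopilot run / replay / bench
docs/methods.md  model, parameters, design choices, limitations
```
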
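# Methods

## The agent model

`biopilot` implements an autonomous agent loop for conventional multi-omic
analyses. The user supplies exactly three inputs in a YAML document: an
ordered list of `path: description` data entries, a free-text final
objective, and (optionally) a blacklist of prohibited software. The run
then proceeds through three phases:

1. **Planning.** The backend language model is asked for an ordered,
   step-by-step analysis plan naming the software for each step. The reply
   is parsed into `PlanStep`s; a plan that uses blacklisted software is
   rejected and re-proposed with the violations appended to the prompt.
2. **Code generation.** For each step, the backend is asked for exactly one
   fenced shell code block accomplishing that step's sub-goal.
3. **Execution with automatic code repair (ACR).** The script is screened
   against a command denylist, executed confined to the run workspace, and
   classified. On a classified error, a bounded excerpt of the error text
   is appended to the code-generation prompt and the whole script is
   regenerated — a repetitive cycle until the code executes cleanly or the
   attempt bound is exhausted.

Backend calls are stateless: the full context is re-rendered into every
prompt from four named slots (*blacklist*, *data list*, *current goal*,
*history summary*). The history summary is natural-language memory built
from two fixed sentence templates — one planning-phase sentence
("First, you provided input in the format 'file path: file description' in
a list: … You devised a detailed plan … Your overarching goal is … Your
plan involves …") and one sentence per completed task ("Then, you
successfully completed the task: … with the corresponding code: …").
Only *successfully* completed steps enter the memory, so failed attempts
never pollute later prompts.

## Tunable parameters

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| `max_repair_attempts` | 5 | regenerations | An unbounded repair cycle cannot terminate against a stuck backend; 5 regenerations bound the loop at 6 executions per step while leaving room for multi-cause failures. 0 disables ACR. |
| `decoding_temperature` | 0 | — | Deterministic decoding for reproducibility. |
| `step_timeout` | 3600 | s | Generous for real pipelines; fixtures override nothing (stub tools finish in milliseconds). |
| history token budget | unlimited | tokens (≈4 chars each) | When set, oldest completed-task sentences are elided oldest-first and replaced by a count marker; the plan sentence and the most recent task sentence are always retained. The 4-chars-per-token proxy avoids a tokenizer dependency. |
| error excerpt cap | 4000 | chars | Tail-biased (stderr tail, then stdout tail): shell errors trail, and unbounded feedback would overflow the context. |
| capture limit | 1 MiB | bytes/stream | Tail-preserving truncation, flagged on the result. |

## Error classification

A run of a step is an error iff the exit status is non-zero, the script
timed out (exit sentinel 124, the GNU-timeout convention), or a configured
error pattern ("command not found", "No such file or directory",
"Traceback", "Error:", "error:", "Segmentation fault", "Killed") matches
either captured stream. Plain stderr non-emptiness is deliberately *not* an
error signal: many aligners and trimmers log progress to stderr. The
classification is a pure function of the captured result and the pattern
list, which is what makes the brute-force oracle test possible.

## Sandboxing

Generated scripts are screened line-wise (comments and here-doc bodies
excluded) against a denylist of regex patterns: `sudo`/`su`,
`shutdown`/`reboot`, `mkfs*`, `dd` onto block devices, `rm`/`chmod`/`chown`
on absolute paths outside the workspace, and `curl`/`wget` piped into a
shell. A rejection is surfaced to the repair loop as a
`denylisted_command` error finding — the agent regenerates rather than
aborts — and a rejected script is never executed. Accepted scripts run
under `bash` with `set -e` prepended (fail-fast: a multi-command step
reports the first failing command), working directory pinned to the
workspace root, `HOME` and `TMPDIR` remapped into the workspace, and an
allow-listed environment. Container mode (bind-mounting only the
workspace into a `docker`/`podman` container) is available but off by
default; confinement in the default mode rests on working-directory
discipline plus the denylist, and the test suite audits it by snapshot
diff. Network policy is not enforced — real runs legitimately install
tools from conda channels.

## Transcript backend

The test double answers prompts from a recorded matcher → response table.
Prompts are whitespace-normalized and run-specific tokens (workspace path,
run id) are replaced by declared placeholders before matching, so a
transcript replays in any temporary directory. Matchers are either an
exact SHA-256 of the normalized prompt or a substring pattern; entries are
matched in file order among entries with remaining uses. A finite
`max_uses` on an earlier entry lets a later entry with the same matcher
take over — this is how repair transcripts return broken code on the first
request and fixed code on regeneration. Validation rejects an entry that
can never be reached (an earlier identical matcher with unlimited uses).

## Plan parsing

Planner output has no guaranteed grammar; two splitters are run and the
one recognizing more steps wins (tie → the numbered parse, as the more
explicit): explicit numbering (`1.` / `2)` at line starts) and ordinal
connectives (First / Next / Then / After that / Finally / …) at sentence
starts. Software names are taken from quoted tokens (kept even when
unknown) plus a bundled, extensible lexicon of ~70 common bioinformatics
tools matched case-insensitively on word boundaries; file paths by
pattern. One step per plan sentence; multi-tool sentences are not split
further.

## The evaluation registry

The bundled registry (`data/case_registry.csv`) holds 40 real-world
analysis cases across genomics (15), transcriptomics (23), proteomics (1)
and metabolomics (1), with expert-judged pass/fail outcomes per stage for
the no-repair variant, the stated failure reason, the tools chosen, and
the planning time. Stage outcomes obey the implication chain (execute ⇒
codegen ⇒ plan), enforced at load. For the with-repair variant only
aggregate counts were published (36 / 35 / 35 of 40). Two cells are
derivable: since the with-repair codegen and execute counts are equal,
every case that generated code also executed, so all seven execute-stage
failures of the no-repair variant flip to pass. Which two of the three
codegen failures (9.1, 10.6, 10.8) were recovered is not attributable;
those cells are stored as `unknown` and the summarizer resolves them
against `data/acr_aggregates.json` after checking that
known-passes ≤ aggregate ≤ known-passes + unknowns. Percentages are
computed in exact rational arithmetic and rounded to one decimal.

## Synthetic fixtures

Three fixture kinds exercise the full loop hermetically:

* `rnaseq_deg` — four single-end samples (two conditions, two replicates),
  a five-step differential-expression pipeline (trim → align → sort →
  count → test) with one injected failure: the aligner is first invoked
  without building its genome index, and the scripted repair response
  prepends the index build. 50 reads × 60 bp per sample, a 2 kb reference,
  a 2-gene GTF.
* `chipseq_peaks` — two samples, four-step peak-calling pipeline, no
  failure.
* `generic_fail_repair` — a minimal two-step run whose second step fails
  once (a tool demanding a flag the first script omits) and is repaired.

Reads are generated by an explicitly specified linear congruential
generator (`state' = (1103515245·state + 12345) mod 2³¹`) so that
`(kind, seed)` fully determines every payload byte independent of Python's
RNG; gzip members are written with `mtime=0` and an empty embedded
filename for the same reason. External tools are stubbed by shell scripts
inside the fixture's `bin/` directory that mimic the real tools'
command-line surface but only shuffle bytes. Every file named after a real
accession or genome (`SRR…`, `mm39.fa`, `hg38.fa`) is a synthetic
stand-in produced by the generator.

What passing fixture tests therefore show: the *agent loop* — planning,
prompt/memory discipline, code extraction, screening, confined execution,
error classification, bounded repair, fail-stop orchestration and
reporting — behaves correctly and deterministically. What they do not
show: that any live language model produces good plans or working code for
real data, that real aligners/counters behave like the stubs, or that the
published success rates would be reproduced by a live backend; those rates
enter this package only as the transcribed registry.

## Numerical and design choices

* Problem sizes: fixture runs use 40–50 reads per sample and 1.5–2 kb
  references; the benchmark runs 3 kinds × 2 seeds. These sizes keep a
  full suite run in seconds while still exercising every code path,
  including gzip round-trips and multi-file steps.
* Fail-stop orchestration: after a step exhausts its repair budget the
  remaining steps are marked `skipped`, never executed — downstream omics
  steps consume upstream outputs, so best-effort continuation would be
  meaningless. There is no mid-run re-planning.
* Stage flags: `plan_ok` (a plan was accepted), `all_codegen_ok` (every
  plan step produced at least one script), `end_to_end_ok` (every step
  succeeded); the implication chain end_to_end ⇒ codegen ⇒ plan holds by
  construction.
* The empty blacklist slot renders as the literal marker `none` and an
  empty history as `no prior actions`; consequently a blacklist entry
  literally named "none" (or a history equal to the marker) is not
  representable — a documented, deliberate corner of the slot round-trip.
* Data paths may not contain `": "`, which is the data-list rendering
  delimiter; entries are single-line.
* The default blacklist ships empty: the choice of tools to ban is a
  site-specific judgement, so it must be user-supplied.
* Degenerate inputs: an empty history renders the marker; a zero-step
  parse is an error (never an empty plan); `max_repair_attempts=0`
  disables repair (exactly one execution per step); exhaustion is a
  reported outcome, never an exception.

## Known limitations

* The live chat-API adapter and the local subprocess adapter are thin and
  untested against real services (the offline suite never touches the
  network); they share the backend contract with the transcript player,
  which the substitution tests rely on.
* Command screening is line-oriented regex matching; an adversarial script
  can evade it (e.g. via variable indirection). Screening is a guard
  against accident-grade damage, not a security boundary — container mode
  exists for the latter.
* Software recognition in plans depends on quoting conventions and the
  lexicon; an unquoted, unknown tool name is not recognized and thus not
  blacklist-checkable.
* The with-repair registry summarization rests on published aggregates for
  three cells, as described above; per-case with-repair ground truth does
  not exist in the source material.
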
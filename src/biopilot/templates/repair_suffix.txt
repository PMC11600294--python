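
=== PREVIOUS ATTEMPT ===
{previous_code}
=== OBSERVED ERROR ===
{error_excerpt}
=== REPAIR INSTRUCTIONS ===
The shell code in PREVIOUS ATTEMPT failed with the error shown in OBSERVED
ERROR. Diagnose the cause and produce a corrected, complete replacement.
Answer with exactly one fenced shell code block (```bash ... ```).
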
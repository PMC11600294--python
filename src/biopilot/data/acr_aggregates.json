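{
  "variant": "with_acr",
  "plan": 36,
  "codegen": 35,
  "execute": 35,
  "note": "Aggregate stage pass counts for the with-repair variant. The per-case breakdown was published only in aggregate: of the three code-generation failures of the no-repair variant (cases 9.1, 10.6, 10.8), exactly two were recovered by automatic code repair, but which two is not attributable, so those cases carry 'unknown' in the registry and the summarizer falls back to these counts after a consistency check."
}
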
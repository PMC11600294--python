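You are an expert bioinformatician. Using only the information in the
delimited sections below, devise a complete analysis plan for the user's
data and final objective.

=== BLACKLIST ===
{blacklist}
=== DATA LIST ===
{data_list}
=== CURRENT GOAL ===
{current_goal}
=== HISTORY SUMMARY ===
{history_summary}
=== INSTRUCTIONS ===
Produce an ordered, numbered list of analysis steps (1., 2., ...). For each
step name the software to use (quote every tool name, e.g. "Hisat2") and the
input files it consumes. Cover the whole analysis from preprocessing to the
final objective. Never use any software on the blacklist.
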
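# Per-term phene-pattern category overrides: term_id <TAB> category
# Categories: object-morphology | temporal-object | process | disposition | relational
# APO:0000253 (cell cycle progression) uses the simple bearer form in its
# published annotation expression; part-of reflexivity keeps its inferences.
APO:0000253	disposition
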
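# Structured-abstract section heading -> canonical discourse label.
# Tab-separated, headings matched case-insensitively after stripping
# trailing colons.  Unmapped headings cause the citation to be skipped
# during label distillation.
BACKGROUND	Background
INTRODUCTION	Background
CONTEXT	Background
OBJECTIVE	Objective
OBJECTIVES	Objective
AIM	Objective
AIMS	Objective
PURPOSE	Objective
GOAL	Objective
GOALS	Objective
METHODS	Methods
METHOD	Methods
MATERIALS AND METHODS	Methods
PATIENTS AND METHODS	Methods
DESIGN	Methods
STUDY DESIGN	Methods
PROCEDURES	Methods
RESULTS	Results
FINDINGS	Results
RESULT	Results
CONCLUSIONS	Conclusions
CONCLUSION	Conclusions
INTERPRETATION	Conclusions
DISCUSSION	Conclusions
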
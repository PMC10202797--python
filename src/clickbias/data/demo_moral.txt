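# Demo moral word list (open, for tests and examples only).
moral
immoral
justice
unjust
duty
honor
honour
virtue
sin
sinful
righteous
evil
sacred
corrupt
fair
unfair
guilt
blame
deserve
betray
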
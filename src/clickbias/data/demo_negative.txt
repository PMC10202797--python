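# Demo negative word list (open, for tests and examples only).
wrong
bad
awful
ugly
sad
angry
fear
afraid
terrible
horrible
crushed
heartbreaking
troubling
harm
obsess
fake
ridiculous
missing
shame
hate
hated
worst
cruel
disaster
painful
hurt
broken
failure
scared
embarrassed
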
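# Demo positive word list (open, for tests and examples only).
love
loved
loves
pretty
beautiful
happy
happiness
good
great
wonderful
kind
support
favorite
favourite
laughed
laugh
joyful
amazing
brilliant
hope
hopeful
win
wins
best
sweet
smile
delight
benefit
inspiring
charming
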
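angry	anger	1
rage	anger	1
furious	anger	1
outrage	anger	1
mad	anger	1
hate	anger	1
fury	anger	1
hostile	anger	1
expect	anticipation	1
await	anticipation	1
eager	anticipation	1
forecast	anticipation	1
upcoming	anticipation	1
plan	anticipation	1
disgust	disgust	1
gross	disgust	1
filthy	disgust	1
rotten	disgust	1
vile	disgust	1
nasty	disgust	1
fear	fear	1
afraid	fear	1
scared	fear	1
terror	fear	1
panic	fear	1
dread	fear	1
horror	fear	1
threat	fear	1
joy	joy	1
happy	joy	1
delight	joy	1
cheer	joy	1
glee	joy	1
bliss	joy	1
laugh	joy	1
sad	sadness	1
grief	sadness	1
sorrow	sadness	1
mourn	sadness	1
heartbreaking	sadness	1
tearful	sadness	1
crushed	sadness	1
surprise	surprise	1
shock	surprise	1
astonish	surprise	1
sudden	surprise	1
unexpected	surprise	1
stunned	surprise	1
trust	trust	1
faith	trust	1
loyal	trust	1
reliable	trust	1
honest	trust	1
sincere	trust	1
calm	trust	0
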
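not
no
never
none
cannot
cant
can't
dont
don't
didnt
didn't
doesnt
doesn't
isnt
isn't
wasnt
wasn't
wont
won't
wouldnt
wouldn't
couldnt
couldn't
shouldnt
shouldn't
aint
ain't
without
nothing
neither
nor
hardly
scarcely
rarely
seldom
nope
nowhere
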
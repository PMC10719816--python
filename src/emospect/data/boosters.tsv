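# booster	increment
very	0.293
really	0.293
extremely	0.305
absolutely	0.293
incredibly	0.293
totally	0.293
completely	0.293
so	0.293
truly	0.293
remarkably	0.293
exceptionally	0.293
especially	0.293
particularly	0.293
slightly	-0.293
somewhat	-0.293
marginally	-0.293
barely	-0.293
kinda	-0.293
sorta	-0.293
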
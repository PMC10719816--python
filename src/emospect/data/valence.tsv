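# term	valence
good	1.9
great	3.1
excellent	2.7
awesome	3.1
fantastic	2.6
wonderful	2.7
superb	3.0
perfect	2.7
brilliant	2.8
beautiful	2.1
incredible	2.4
magnificent	2.8
marvelous	2.7
splendid	2.6
terrific	2.6
outstanding	2.8
remarkable	2.0
effective	2.1
works	1.7
worked	1.7
working	1.6
nice	1.8
better	1.9
best	3.2
recommend	1.5
recommended	1.5
pleased	2.0
pleasing	1.9
satisfied	2.0
satisfying	2.2
satisfaction	2.0
improvement	1.6
improved	1.7
improve	1.5
helps	1.6
helped	1.6
helpful	1.8
impressive	2.2
impressed	2.1
strong	1.4
stronger	1.5
reliable	1.7
comfortable	1.4
easy	1.6
easier	1.5
smooth	1.3
success	2.1
successful	2.2
positive	1.9
beneficial	1.9
benefit	1.5
confidence	1.7
confident	1.9
enjoy	1.9
enjoyed	2.0
enjoyable	2.1
favorite	2.0
worthwhile	1.9
glad	2.0
grateful	2.3
thankful	2.1
appreciate	1.9
appreciated	1.9
solid	1.2
super	2.9
decent	1.1
fine	0.8
okay	0.9
ok	0.9
alright	1.0
acceptable	1.0
adequate	0.8
pleasant	1.8
refreshing	1.7
energetic	1.5
healthy	1.6
safe	1.4
gentle	1.1
convenient	1.4
affordable	1.2
like	1.5
liked	1.6
upbeat	1.8
relief	1.9
relieved	1.9
tolerable	0.5
passable	0.4
fair	0.4
modest	0.3
mild	0.2
workable	0.6
manageable	0.5
usable	0.4
presentable	0.3
bad	-2.5
terrible	-2.9
horrible	-2.5
awful	-2.0
worst	-3.1
worse	-2.1
useless	-1.8
ineffective	-1.7
poor	-1.6
nasty	-1.9
unpleasant	-1.7
harsh	-1.3
severe	-1.4
painful	-1.9
pain	-1.7
ache	-1.4
headache	-1.1
nausea	-1.5
dizzy	-1.0
problem	-1.2
problems	-1.2
issue	-0.8
issues	-0.8
fail	-2.0
failed	-2.0
failure	-2.1
disaster	-2.5
mess	-1.4
regret	-1.8
unbearable	-2.3
intolerable	-2.1
weak	-1.2
weaker	-1.2
expensive	-0.9
costly	-0.8
overpriced	-1.3
waste	-1.8
wasted	-1.8
embarrassing	-1.6
embarrassed	-1.6
uncomfortable	-1.4
difficult	-1.2
trouble	-1.4
troublesome	-1.5
risky	-1.1
dangerous	-1.8
damage	-1.6
harmful	-1.7
sick	-1.5
ill	-1.4
vomit	-1.9
blurry	-0.9
blurred	-0.9
stuffy	-0.8
congestion	-0.7
insomnia	-1.2
sleepless	-1.2
negative	-1.6
unreliable	-1.6
inconsistent	-1.0
mediocre	-0.8
lousy	-1.9
pathetic	-1.8
junk	-1.5
garbage	-1.8
scam	-2.2
ripoff	-2.0
hate	-2.7
hated	-2.7
dislike	-1.6
disliked	-1.6
upset	-1.6
iffy	-0.5
subpar	-0.6
underwhelming	-0.5
meager	-0.4
bland	-0.3
dull	-0.6
lacking	-0.5
clunky	-0.4
spotty	-0.3
patchy	-0.2
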
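# sentitrace packaged valence lexicon (synthetic fixture scale, ~300 terms)
# term<TAB>valence, valence in [-4, +4]; sections #BOOSTERS / #NEGATORS follow.
# Terms are lowercase and unique across all three tables. This dictionary is
# an original, deliberately small vocabulary for testing and simulation; it
# is not a copy of any third-party lexicon.
abandon	-1.9
admirable	2.6
admire	2.2
adore	2.9
afraid	-2.0
aggressive	-1.4
alarm	-1.6
alarming	-2.1
amazing	2.8
angry	-2.3
annoy	-1.6
annoying	-1.8
anxious	-1.9
appalling	-2.9
appreciate	1.9
assure	1.4
attack	-2.1
awesome	3.1
awful	-2.7
bad	-2.5
beautiful	2.9
benefit	1.7
best	3.2
betray	-2.8
better	1.9
blame	-1.7
bless	2.3
bogus	-1.9
boring	-1.3
breach	-2.4
brilliant	3.0
broken	-1.9
bug	-1.3
bully	-2.5
calm	1.3
care	2.0
careless	-1.8
catastrophe	-3.3
celebrate	2.7
cheat	-2.6
cheerful	2.5
chaos	-2.6
clean	1.6
clever	2.2
comfort	2.0
commend	2.1
complain	-1.6
concern	-1.4
concerned	-1.5
confident	2.2
confuse	-1.3
confusing	-1.5
congratulations	2.9
convenient	1.8
corrupt	-3.0
crash	-2.0
creepy	-2.2
crisis	-2.5
cruel	-2.8
damage	-2.0
danger	-2.4
dangerous	-2.5
dead	-3.1
deceive	-2.7
defect	-1.8
delight	2.8
delighted	3.0
deny	-1.4
depressed	-2.6
despair	-2.8
destroy	-2.9
die	-3.2
dirty	-1.8
disappoint	-2.2
disappointing	-2.3
disaster	-3.1
dishonest	-2.6
dislike	-1.7
dismal	-2.2
distress	-2.3
doom	-2.7
doubt	-1.2
dread	-2.4
dreadful	-2.8
easy	1.4
effective	1.9
efficient	1.9
embarrassing	-1.9
encourage	1.9
enjoy	2.3
enthusiastic	2.4
error	-1.5
evil	-3.3
excellent	3.0
excited	2.4
exciting	2.3
fabulous	2.9
fail	-2.3
failure	-2.5
fair	1.5
faith	1.8
fake	-2.1
fantastic	3.0
fault	-1.6
faulty	-1.9
favorite	2.1
fear	-2.2
fine	1.1
flaw	-1.7
flawed	-1.9
fraud	-2.9
free	1.4
fresh	1.3
friendly	2.2
frighten	-2.3
frustrating	-2.1
fun	2.2
furious	-2.7
generous	2.3
gentle	1.8
glad	2.0
gloomy	-1.9
good	1.9
grateful	2.4
great	2.7
grief	-2.7
gross	-2.1
happy	2.6
harm	-2.2
harmful	-2.3
hate	-2.9
hazard	-2.1
heal	1.9
healthy	2.0
help	1.7
helpful	2.1
helpless	-2.0
hero	2.6
honest	2.3
hope	1.9
hopeful	2.2
hopeless	-2.4
horrible	-2.9
horrific	-3.1
hostile	-2.3
hurt	-2.2
ideal	2.4
improve	1.8
improvement	1.8
incompetent	-2.4
ineffective	-1.9
inspire	2.3
intrusive	-2.1
invasive	-2.0
joy	2.9
kind	2.1
lazy	-1.5
liar	-2.8
lie	-2.3
lose	-1.8
loss	-1.9
love	3.0
lovely	2.8
loyal	2.2
lucky	2.1
mad	-2.2
magnificent	3.0
menace	-2.3
mess	-1.7
miserable	-2.7
mislead	-2.4
misleading	-2.4
mistake	-1.7
misuse	-1.9
nasty	-2.4
neglect	-2.0
nervous	-1.8
nice	1.8
noble	2.2
obstacle	-1.4
offend	-2.0
optimistic	2.3
outrage	-2.6
outstanding	3.1
overreach	-1.8
panic	-2.5
peace	2.4
peaceful	2.4
perfect	3.1
pleasant	2.2
please	1.4
pleased	2.1
positive	2.0
praise	2.4
pretty	1.9
problem	-1.6
progress	1.8
promise	1.4
promising	2.0
protect	1.9
protection	1.8
proud	2.3
rage	-2.7
reassure	1.9
reassuring	2.1
rejoice	2.8
relief	2.1
relieve	1.9
remarkable	2.5
rescue	2.1
resent	-2.1
respect	2.2
rigged	-2.4
risk	-1.5
risky	-1.8
rotten	-2.4
rude	-2.1
ruin	-2.5
sad	-2.3
safe	1.9
safeguard	1.8
satisfied	2.1
scam	-2.9
scandal	-2.5
scare	-2.2
scared	-2.3
scary	-2.2
secure	1.9
severe	-1.8
shame	-2.2
shameful	-2.5
sick	-2.0
smart	2.1
smooth	1.6
solid	1.4
sorrow	-2.5
sorry	-1.1
splendid	2.8
spy	-2.0
spying	-2.2
steal	-2.5
stress	-1.9
stressful	-2.1
strong	1.9
stupid	-2.4
succeed	2.3
success	2.5
successful	2.5
suffer	-2.4
suffering	-2.5
super	2.6
superb	3.0
support	1.8
supportive	2.1
sweet	2.1
terrible	-2.8
terrific	2.9
terrify	-3.0
thank	1.9
thankful	2.3
thanks	1.8
threat	-2.3
threaten	-2.4
thrilled	2.9
toxic	-2.5
tragedy	-3.0
tragic	-2.9
trouble	-1.8
trust	2.0
trusted	2.1
trustworthy	2.4
ugly	-2.2
unacceptable	-2.4
uncomfortable	-1.7
unfair	-2.2
unhappy	-2.2
unreliable	-2.0
unsafe	-2.1
upset	-2.0
useful	1.9
useless	-2.1
valuable	2.0
victory	2.7
vital	1.6
warm	1.8
waste	-1.9
weak	-1.5
welcome	1.9
win	2.5
wonderful	2.9
worry	-1.9
worried	-2.0
worse	-2.3
worst	-3.3
worthless	-2.6
wrong	-1.9
#BOOSTERS
absolutely	0.293
amazingly	0.282
completely	0.262
deeply	0.262
especially	0.225
extremely	0.293
hugely	0.290
incredibly	0.293
majorly	0.276
particularly	0.213
purely	0.239
really	0.267
remarkably	0.272
seriously	0.258
so	0.211
terribly	0.276
thoroughly	0.268
totally	0.276
truly	0.272
utterly	0.304
very	0.293
#NEGATORS
ain't
aint
barely
can't
cannot
cant
couldn't
couldnt
didn't
didnt
doesn't
doesnt
don't
dont
hardly
isn't
isnt
neither
never
no
nobody
none
nope
not
nothing
nowhere
rarely
scarcely
shouldn't
shouldnt
wasn't
wasnt
without
won't
wont
wouldn't
wouldnt
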
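the	22038615
be	12545825
and	10741073
of	10343885
a	10144200
in	6996437
to	6332195
have	4303955
it	3872477
i	3978265
that	3430996
for	3281454
you	3081151
he	2909254
with	2683014
on	2485306
do	2573587
say	1915138
this	1885366
they	1689347
at	1413021
we	1512161
his	1532935
from	1275139
so	1182682
not	1157166
by	1113667
she	1484869
or	1088530
as	1096284
what	908207
go	1151045
their	782849
can	803705
who	798191
get	992596
if	889619
would	618580
her	969591
all	825201
my	918278
make	857168
about	754591
know	683475
will	659221
up	794755
one	700771
time	574925
out	750253
there	689663
see	516514
new	416432
just	555933
now	464955
like	625063
take	488971
him	498834
them	446023
into	385303
year	366834
your	444444
good	379941
some	387717
could	349479
day	344242
no	342785
us	330486
but	999963
over	304559
think	296996
also	254682
back	320161
after	268873
use	319702
two	282613
how	289382
our	281513
work	311405
first	234265
well	249571
way	214779
even	229370
want	249128
because	227035
any	214005
these	196635
give	216848
most	167611
game	117406
team	106432
play	157436
player	54923
win	51332
season	41221
league	26896
coach	27820
fan	22644
score	16417
goal	24059
match	21245
cup	13798
world	208798
sport	23761
football	29631
soccer	8571
hockey	9400
baseball	10021
basketball	11088
rugby	4100
boxing	4150
fight	32567
fighter	6213
knockout	1200
round	35760
ring	11600
field	48213
ice	13400
puck	900
ball	27500
helmet	1800
head	95307
brain	17800
injury	13900
injured	6900
hurt	13200
pain	20100
ache	450
headache	2900
concussion	1100
concussed	180
protocol	2300
symptom	4100
doctor	23900
hospital	19300
medical	14800
health	43900
safety	13100
risk	24700
danger	5900
dangerous	8700
recover	4300
recovery	6800
rest	18900
return	25800
hit	35400
hitting	4900
knock	3200
knocked	2800
cold	17800
out	750253
tough	7900
toughness	420
brave	3400
stupid	6300
stupidity	700
smart	8900
serious	19800
seriously	7800
awareness	3900
aware	7400
care	38900
careful	5400
concern	13900
concerned	9800
worry	11900
worried	8100
scary	2900
scared	5300
fear	13700
glad	6300
happy	37900
sad	10100
angry	7900
mad	6900
love	76500
hate	14900
like	625063
enjoy	11900
enjoyed	3900
great	88900
good	379941
bad	58900
terrible	7900
awful	4900
horrible	4900
amazing	17900
awesome	9900
nice	33900
cool	20900
fine	22900
okay	16900
ok	22900
wow	5900
yay	1300
damn	6900
hell	13900
big	91900
biggest	9900
small	57900
old	98900
young	49900
man	124900
woman	79900
kid	29900
boy	37900
girl	49900
guy	43900
people	178900
news	56900
update	6900
watch	33900
watching	13900
live	39900
video	21900
photo	10900
story	40900
read	37900
today	56900
tonight	11900
yesterday	13900
tomorrow	13900
night	84900
morning	29900
week	76900
month	42900
hour	38900
minute	27900
second	51900
last	118900
next	97900
off	211900
again	106900
still	107900
never	88900
always	69900
really	64900
very	191900
much	166900
more	336900
here	116900
home	77900
away	58900
left	39900
right	110900
down	189900
come	135900
came	40900
look	95900
looking	29900
feel	46900
feeling	13900
felt	20900
think	296996
thought	49900
said	196900
told	36900
talk	27900
talking	13900
need	85900
needs	16900
keep	49900
stop	31900
start	43900
started	20900
end	59900
ended	6900
leave	29900
leaving	9900
miss	16900
missed	8900
lost	30900
lose	14900
losing	7900
won	23900
winning	10900
beat	13900
beaten	3900
clean	13900
cleaned	2300
clock	5900
bell	3900
rung	500
wake	6900
woke	3900
sleep	17900
offseason	700
preseason	600
playoff	2900
final	23900
finals	2900
champion	6900
championship	4900
title	14900
record	23900
stats	2900
referee	1900
ref	1900
penalty	4900
foul	1900
tackle	2300
tackled	900
check	19900
checking	4900
substitute	1400
substituted	400
bench	3400
sideline	900
sidelined	700
quarterback	1900
linebacker	700
goalie	900
keeper	1900
defender	1900
striker	1300
midfielder	900
captain	8900
rookie	1900
veteran	5900
hello	7900
hey	13900
bye	2900
thanks	23900
thank	26900
please	29900
sorry	16900
yes	61900
yeah	23900
maybe	33900
sure	52900
definitely	8900
probably	25900
actually	38900
literally	8900
absolutely	8900
totally	8900
apparently	6900
honestly	4900
hopefully	3900
finally	16900
already	37900
almost	32900
enough	42900
little	81900
lot	42900
many	119900
few	60900
every	72900
each	67900
both	67900
another	67900
other	186900
same	100900
different	52900
own	78900
real	38900
true	29900
wrong	23900
fake	3900
faking	700
confirmed	4900
reported	11900
report	23900
unreported	200
placed	8900
list	23900
rule	19900
rules	12900
law	35900
change	56900
changed	16900
better	73900
worse	13900
worst	10900
best	91900
hard	55900
harder	8900
easy	29900
easier	9900
fast	23900
slow	16900
quick	13900
player	54923
played	27900
playing	27900
plays	9900
games	31900
teams	16900
players	23900
heads	9900
hits	6900
injuries	5900
concussions	500
helmets	600
brains	2900
symptoms	3900
doctors	8900
bellator	1200
mma	2400
ufc	2600
nhl	3400
nfl	4400
mlb	2900
nba	3900
fifa	2400
worldcup	900
concussionprotocol	100
headsup	200
playersafety	150
build	48900
building	35900
built	21900
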
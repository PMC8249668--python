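amazing	a	0.85	0.03	0.12
aware	a	0.55	0.09	0.36
awareness	n	0.55	0.09	0.36
awesome	a	0.85	0.03	0.12
best	a	0.8	0.04	0.16
better	a	0.6	0.08	0.32
brave	a	0.65	0.07	0.28
care	v	0.55	0.09	0.36
careful	a	0.6	0.08	0.32
celebrate	v	0.65	0.07	0.28
champion	n	0.55	0.09	0.36
cool	a	0.65	0.07	0.28
courage	n	0.65	0.07	0.28
delighted	a	0.8	0.04	0.16
encouraging	a	0.65	0.07	0.28
enjoy	v	0.7	0.06	0.24
epic	a	0.6	0.08	0.32
excellent	a	0.85	0.03	0.12
fantastic	a	0.8	0.04	0.16
fine	a	0.55	0.09	0.36
glad	a	0.7	0.06	0.24
good	a	0.75	0.05	0.2
grateful	a	0.7	0.06	0.24
great	a	0.8	0.04	0.16
happy	a	0.8	0.04	0.16
heal	v	0.6	0.08	0.32
health	n	0.5	0.1	0.4
healthy	a	0.65	0.07	0.28
helpful	a	0.65	0.07	0.28
hope	v	0.6	0.08	0.32
hopeful	a	0.6	0.08	0.32
important	a	0.55	0.09	0.36
improve	v	0.6	0.08	0.32
love	v	0.8	0.04	0.16
nice	a	0.7	0.06	0.24
okay	a	0.5	0.1	0.4
perfect	a	0.8	0.04	0.16
positive	a	0.7	0.06	0.24
praise	v	0.65	0.07	0.28
protect	v	0.65	0.07	0.28
protection	n	0.6	0.08	0.32
proud	a	0.7	0.06	0.24
recover	v	0.6	0.08	0.32
recovery	n	0.6	0.08	0.32
relieved	a	0.6	0.08	0.32
respect	n	0.65	0.07	0.28
responsible	a	0.6	0.08	0.32
right	a	0.5	0.1	0.4
safe	a	0.6	0.08	0.32
safety	n	0.55	0.09	0.36
sensible	a	0.6	0.08	0.32
serious	a	0.5	0.1	0.4
smart	a	0.65	0.07	0.28
strong	a	0.55	0.09	0.36
support	v	0.6	0.08	0.32
thank	v	0.7	0.06	0.24
thanks	n	0.7	0.06	0.24
well	r	0.55	0.09	0.36
win	v	0.6	0.08	0.32
winner	n	0.6	0.08	0.32
wise	a	0.6	0.08	0.32
wonderful	a	0.8	0.04	0.16
wow	u	0.5	0.1	0.4
yay	u	0.7	0.06	0.24
ache	n	0.09	0.55	0.36
angry	a	0.06	0.7	0.24
annoying	a	0.08	0.6	0.32
awful	a	0.03	0.85	0.12
bad	a	0.05	0.75	0.2
brutal	a	0.07	0.65	0.28
careless	a	0.07	0.65	0.28
cheat	v	0.06	0.7	0.24
concern	n	0.11	0.45	0.44
concerned	a	0.11	0.45	0.44
crazy	a	0.1	0.5	0.4
cruel	a	0.06	0.7	0.24
damn	u	0.1	0.5	0.4
danger	n	0.08	0.6	0.32
dangerous	a	0.07	0.65	0.28
dirty	a	0.08	0.6	0.32
disappointed	a	0.07	0.65	0.28
disaster	n	0.06	0.7	0.24
disgrace	n	0.06	0.7	0.24
disregard	v	0.08	0.6	0.32
dumb	a	0.05	0.75	0.2
fail	v	0.07	0.65	0.28
failure	n	0.07	0.65	0.28
fake	a	0.08	0.6	0.32
faking	v	0.08	0.6	0.32
fear	n	0.08	0.6	0.32
hate	v	0.04	0.8	0.16
headache	n	0.09	0.55	0.36
hell	n	0.1	0.5	0.4
horrible	a	0.03	0.85	0.12
hurt	v	0.08	0.6	0.32
ignorant	a	0.06	0.7	0.24
ignore	v	0.09	0.55	0.36
injured	a	0.1	0.5	0.4
injury	n	0.1	0.5	0.4
insane	a	0.09	0.55	0.36
lose	v	0.09	0.55	0.36
loser	n	0.06	0.7	0.24
loss	n	0.09	0.55	0.36
mad	a	0.07	0.65	0.28
nasty	a	0.07	0.65	0.28
pain	n	0.08	0.6	0.32
painful	a	0.07	0.65	0.28
pathetic	a	0.05	0.75	0.2
reckless	a	0.06	0.7	0.24
ridiculous	a	0.08	0.6	0.32
sad	a	0.06	0.7	0.24
scared	a	0.08	0.6	0.32
scary	a	0.07	0.65	0.28
shame	n	0.07	0.65	0.28
shameful	a	0.06	0.7	0.24
stupid	a	0.04	0.8	0.16
stupidity	n	0.04	0.8	0.16
suck	v	0.06	0.7	0.24
terrible	a	0.03	0.85	0.12
toxic	a	0.07	0.65	0.28
ugly	a	0.08	0.6	0.32
violence	n	0.07	0.65	0.28
violent	a	0.07	0.65	0.28
worried	a	0.09	0.55	0.36
worry	v	0.09	0.55	0.36
worse	a	0.06	0.7	0.24
worst	a	0.04	0.8	0.16
wrong	a	0.08	0.6	0.32
ball	n	0.05	0.05	0.9
baseball	n	0.05	0.05	0.9
basketball	n	0.05	0.05	0.9
bench	n	0.05	0.05	0.9
boxing	n	0.05	0.05	0.9
brain	n	0.05	0.05	0.9
captain	n	0.05	0.05	0.9
coach	n	0.05	0.05	0.9
cup	n	0.05	0.05	0.9
day	n	0.05	0.05	0.9
defender	n	0.05	0.05	0.9
doctor	n	0.05	0.05	0.9
fact	n	0.05	0.05	0.9
fan	n	0.05	0.05	0.9
field	n	0.05	0.05	0.9
final	n	0.05	0.05	0.9
football	n	0.05	0.05	0.9
game	n	0.05	0.05	0.9
goal	n	0.05	0.05	0.9
goalie	n	0.05	0.05	0.9
guy	n	0.05	0.05	0.9
head	n	0.05	0.05	0.9
helmet	n	0.05	0.05	0.9
hockey	n	0.05	0.05	0.9
home	n	0.05	0.05	0.9
hospital	n	0.05	0.05	0.9
hour	n	0.05	0.05	0.9
ice	n	0.05	0.05	0.9
keeper	n	0.05	0.05	0.9
kid	n	0.05	0.05	0.9
law	n	0.05	0.05	0.9
league	n	0.05	0.05	0.9
level	n	0.05	0.05	0.9
list	n	0.05	0.05	0.9
man	n	0.05	0.05	0.9
match	n	0.05	0.05	0.9
medical	n	0.05	0.05	0.9
minute	n	0.05	0.05	0.9
morning	n	0.05	0.05	0.9
news	n	0.05	0.05	0.9
night	n	0.05	0.05	0.9
number	n	0.05	0.05	0.9
part	n	0.05	0.05	0.9
penalty	n	0.05	0.05	0.9
people	n	0.05	0.05	0.9
place	n	0.05	0.05	0.9
player	n	0.05	0.05	0.9
playoff	n	0.05	0.05	0.9
protocol	n	0.05	0.05	0.9
puck	n	0.05	0.05	0.9
quarterback	n	0.05	0.05	0.9
record	n	0.05	0.05	0.9
referee	n	0.05	0.05	0.9
report	n	0.05	0.05	0.9
rest	n	0.05	0.05	0.9
return	n	0.05	0.05	0.9
ring	n	0.05	0.05	0.9
rookie	n	0.05	0.05	0.9
round	n	0.05	0.05	0.9
rugby	n	0.05	0.05	0.9
rule	n	0.05	0.05	0.9
score	n	0.05	0.05	0.9
season	n	0.05	0.05	0.9
soccer	n	0.05	0.05	0.9
sport	n	0.05	0.05	0.9
story	n	0.05	0.05	0.9
striker	n	0.05	0.05	0.9
symptom	n	0.05	0.05	0.9
team	n	0.05	0.05	0.9
thing	n	0.05	0.05	0.9
time	n	0.05	0.05	0.9
title	n	0.05	0.05	0.9
today	n	0.05	0.05	0.9
tonight	n	0.05	0.05	0.9
update	n	0.05	0.05	0.9
veteran	n	0.05	0.05	0.9
video	n	0.05	0.05	0.9
watch	n	0.05	0.05	0.9
way	n	0.05	0.05	0.9
week	n	0.05	0.05	0.9
woman	n	0.05	0.05	0.9
world	n	0.05	0.05	0.9
year	n	0.05	0.05	0.9
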
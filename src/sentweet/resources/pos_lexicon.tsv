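the	DT
a	DT
an	DT
this	DT
that	DT|IN
these	DT
those	DT
some	DT
any	DT
no	DT
every	DT
each	DT
all	PDT
both	PDT
half	PDT
such	PDT
i	PRP
you	PRP
he	PRP
she	PRP
it	PRP
we	PRP
they	PRP
me	PRP
him	PRP
her	PRP$|PRP
us	PRP
them	PRP
myself	PRP
yourself	PRP
himself	PRP
herself	PRP
itself	PRP
ourselves	PRP
themselves	PRP
my	PRP$
your	PRP$
his	PRP$
its	PRP$
our	PRP$
their	PRP$
who	WP
whom	WP
whose	WP$
what	WP
which	WDT
when	WRB
where	WRB
why	WRB
how	WRB
and	CC
or	CC
but	CC
nor	CC
yet	CC
so	CC|RB
of	IN
in	IN
on	IN
at	IN
by	IN
for	IN
with	IN
about	IN
against	IN
between	IN
into	IN
through	IN
during	IN
before	IN
after	IN
above	IN
below	IN
from	IN
up	RP|IN
down	RP|IN
out	RP|IN
off	RP|IN
over	IN
under	IN
since	IN
until	IN
while	IN
because	IN
if	IN
than	IN
as	IN
without	IN
to	TO
can	MD
could	MD
will	MD
would	MD
shall	MD
should	MD
may	MD
might	MD
must	MD
be	VB
is	VBZ
am	VBP
are	VBP
was	VBD
were	VBD
been	VBN
being	VBG
have	VBP
has	VBZ
had	VBD
do	VBP
does	VBZ
did	VBD
done	VBN
not	RB
never	RB
n't	RB
always	RB
often	RB
sometimes	RB
usually	RB
really	RB
very	RB
too	RB
also	RB
just	RB
still	RB
already	RB
again	RB
here	RB
there	EX|RB
now	RB
then	RB
today	NN|RB
tonight	NN|RB
yesterday	NN|RB
tomorrow	NN|RB
soon	RB
maybe	RB
perhaps	RB
quite	RB
rather	RB
almost	RB
even	RB
only	RB
well	RB|UH
more	RBR|JJR
most	RBS|JJS
less	RBR|JJR
least	RBS|JJS
good	JJ
bad	JJ
big	JJ
small	JJ
new	JJ
old	JJ
great	JJ
serious	JJ
happy	JJ
sad	JJ
best	JJS
worst	JJS
better	JJR
worse	JJR
bigger	JJR
biggest	JJS
saw	VBD|NN
see	VB
seen	VBN
go	VB
goes	VBZ
went	VBD
gone	VBN
get	VB
got	VBD
gotten	VBN
know	VB
knew	VBD
known	VBN
think	VB
thought	VBD
take	VB
took	VBD
taken	VBN
make	VB
made	VBD
say	VB
said	VBD
come	VB
came	VBD
give	VB
gave	VBD
given	VBN
find	VB
found	VBD
tell	VB
told	VBD
feel	VB
felt	VBD
keep	VB
kept	VBD
leave	VB
left	VBD|JJ
lose	VB
lost	VBD|VBN
win	VB|NN
won	VBD|VBN
hit	VB|NN|VBD
put	VB|VBD
let	VB|VBD
beat	VB|VBD|NN
beaten	VBN
play	VB|NN
build	VB
built	VBD|VBN
wake	VB
woke	VBD
woken	VBN
rung	VBN
rang	VBD
oh	UH
wow	UH
yay	UH
yeah	UH
hey	UH
hello	UH
damn	UH|JJ
please	UH|VB
thanks	NNS|UH
ok	UH|JJ
okay	UH|JJ
one	CD
two	CD
three	CD
four	CD
five	CD
six	CD
seven	CD
eight	CD
nine	CD
ten	CD
first	JJ
second	JJ|NN
third	JJ
percent	NN
etc	FW
etcetera	FW
de	FW
la	FW
el	FW
le	FW
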
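saw	see
seen	see
was	be
were	be
been	be
is	be
am	be
are	be
went	go
gone	go
goes	go
got	get
gotten	get
knew	know
known	know
thought	think
took	take
taken	take
made	make
said	say
came	come
gave	give
given	give
found	find
told	tell
felt	feel
kept	keep
left	leave
lost	lose
won	win
has	have
had	have
did	do
does	do
done	do
built	build
woke	wake
woken	wake
rang	ring
rung	ring
beaten	beat
spoke	speak
spoken	speak
wrote	write
written	write
broke	break
broken	break
chose	choose
chosen	choose
fell	fall
fallen	fall
flew	fly
flown	fly
grew	grow
grown	grow
held	hold
led	lead
met	meet
paid	pay
ran	run
sat	sit
sold	sell
sent	send
stood	stand
threw	throw
thrown	throw
wore	wear
worn	wear
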
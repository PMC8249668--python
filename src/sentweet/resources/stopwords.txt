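a
about
above
after
again
all
am
an
and
any
are
as
at
be
because
been
before
being
below
between
both
by
can
could
did
do
does
doing
down
during
each
few
for
from
further
had
has
have
having
he
her
here
hers
herself
him
himself
his
how
i
if
in
into
is
it
its
itself
just
may
me
might
more
most
must
my
myself
now
of
off
on
once
only
or
other
our
ours
ourselves
out
own
same
shall
she
should
so
some
such
than
that
the
their
theirs
them
themselves
then
there
these
they
this
those
through
to
too
under
until
up
very
was
we
were
what
when
where
which
while
who
whom
why
will
with
would
you
your
yours
yourself
yourselves
ya
u
ur
im
ive
id
youre
hes
shes
theyre
weve
whats
thats
theres
gonna
gotta
wanna
lol
omg
rt
via
amp
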
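# High-frequency function-word stop list used ONLY when selecting clustering
# terms; the semantic space itself is built without any stop list.
a
about
above
after
again
against
all
also
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
but
by
can
cannot
could
did
do
does
doing
dont
down
during
each
either
else
ever
every
few
for
from
further
get
got
had
has
have
having
he
her
here
hers
him
his
how
i
if
in
into
is
it
its
just
like
may
me
might
more
most
much
must
my
myself
neither
never
no
nor
not
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
out
over
own
per
same
she
should
since
so
some
still
such
than
that
the
their
theirs
them
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
upon
us
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
within
without
would
yet
you
your
yours
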
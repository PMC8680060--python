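a
about
after
all
also
an
and
any
are
as
at
be
been
but
by
can
could
did
do
for
from
had
has
have
he
her
his
if
in
into
is
it
its
may
more
most
no
not
of
on
one
only
or
other
our
she
so
some
such
than
that
the
their
them
then
there
these
they
this
to
was
we
were
which
who
will
with
would
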
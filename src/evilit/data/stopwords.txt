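a
about
above
after
again
against
all
also
although
among
an
and
any
are
as
at
based
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
compared
could
did
do
does
doing
down
due
during
each
either
few
for
from
further
had
has
have
having
here
how
however
if
in
into
is
it
its
itself
may
might
more
most
must
neither
no
nor
not
of
off
on
once
only
or
other
our
out
over
own
per
respectively
same
she
should
since
so
some
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
thus
to
too
under
until
up
upon
using
used
use
very
was
we
were
what
when
where
whereas
whether
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
among
along
across
via
versus
vs
et
al
furthermore
moreover
therefore
additionally
significantly
respectively
approximately
revealed
showed
shown
show
shows
observed
observe
found
find
finds
reported
report
reports
identified
identify
performed
perform
suggest
suggests
suggested
indicate
indicates
indicated
demonstrated
demonstrate
demonstrates
associated
conducted
obtained
included
including
include
compared
comparing
detected
detect
analyzed
analyse
analysed
examined
examine
evaluated
evaluate
assessed
assess
measured
measure
collected
collect
carried
determined
determine
investigated
investigate
remained
remain
remains
became
become
becomes
made
make
makes
given
gives
give
taken
take
takes
seen
see
known
know
well
many
several
various
two
three
four
five
six
seven
eight
nine
ten
one
first
second
third
new
high
low
higher
lower
increased
increase
increases
increasing
decreased
decrease
decreases
decreasing
elevated
enriched
reduced
depleted
diminished
abundant
significant
non
was
were
been
being
also
study
studies
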
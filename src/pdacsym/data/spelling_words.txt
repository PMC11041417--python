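# Common-word supplement for the spelling dictionary.
# Every token appearing in the symptom lexicon, context cues and
# abbreviation expansions is added to the dictionary automatically;
# this file supplies frequent clinical and general words beyond those.
a
about
acute
adjusted
after
alert
all
also
and
any
appointment
are
as
at
auscultation
bilaterally
blood
brace
by
care
checked
chest
clear
clinic
conservative
constipation
coughing
comfort
continue
controlled
current
date
day
days
detail
directed
discussed
distress
down
dull
during
exam
explained
fitted
follow
for
four
from
given
good
had
has
have
healed
heart
her
his
home
hospital
immunizations
in
intact
is
it
lab
labs
lungs
man
march
measures
medication
medications
mild
monitor
months
murmur
nagging
new
noted
occasional
of
office
old
on
or
ordered
oriented
over
pending
plan
pressure
prior
rate
recheck
regular
residual
results
reviewed
routine
scar
scheduled
seen
severe
sharp
she
signs
since
six
slowly
some
stable
still
takes
than
that
the
there
they
this
three
time
to
today
two
up
usual
visit
vital
was
week
weeks
well
when
will
woman
year
years
days
diarrhea
distress
include
involving
notes
present
regimen
several
spreading
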
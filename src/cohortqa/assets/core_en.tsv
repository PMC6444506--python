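# surface	canonical_id	concept_type	synonyms	cls
no	not	Not	not|without
and	and	LogicalOperator
or	or	LogicalOperator
after	after	TimeOperator	then|later
before	before	TimeOperator	earlier
count	count	StatisticOperator	how many|number of
average	avg	StatisticOperator	avg|mean
sum	sum	StatisticOperator	total
ratio	ratio	StatisticOperator	proportion
distribution	distribution	StatisticOperator
list	list	StatisticOperator	which
over	gt	ArithmeticOperator	more than|above|exceeds
under	lt	ArithmeticOperator	below|less than
equal	eq	ArithmeticOperator	equals
at least	ge	ArithmeticOperator
at most	le	ArithmeticOperator
to	range	RangeSeparator	-|until
the		Stopword
a		Stopword
an		Stopword
of		Stopword
is		Stopword
are		Stopword
was		Stopword
were		Stopword
what		Stopword
who		Stopword
do		Stopword
did		Stopword
does		Stopword
in		Stopword
that		Stopword
they		Stopword
their		Stopword
how		Stopword
many		Stopword
have		Stopword
has		Stopword
had		Stopword
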
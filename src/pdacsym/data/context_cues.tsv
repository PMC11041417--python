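cue_class	phrase
negation	no
negation	not
negation	denies
negation	denied
negation	deny
negation	without
negation	negative for
negation	neg for
negation	ruled out
negation	rule out
negation	rules out
negation	no evidence of
negation	free of
uncertainty	likely
uncertainty	probable
uncertainty	probably
uncertainty	possible
uncertainty	possibly
uncertainty	presumably
uncertainty	perhaps
uncertainty	questionable
uncertainty	suspected
uncertainty	suspect
uncertainty	may be
uncertainty	might be
uncertainty	could be
uncertainty	may have
uncertainty	might have
uncertainty	concern for
uncertainty	suspicion of
uncertainty	suspicious for
definite	positive for
definite	complains of
definite	complain of
definite	complaint of
definite	complaining of
definite	presents with
definite	presented with
definite	presenting with
definite	reports
definite	reported
definite	reporting
definite	endorses
definite	endorsed
definite	endorsing
definite	admits to
definite	here for
definite	experiencing
definite	suffering from
history	history of
history	hx of
history	years ago
history	year ago
history	months ago
history	month ago
history	in the past
history	previously
non_patient	husband
non_patient	wife
non_patient	spouse
non_patient	mother
non_patient	father
non_patient	mom
non_patient	dad
non_patient	son
non_patient	daughter
non_patient	brother
non_patient	sister
non_patient	aunt
non_patient	uncle
non_patient	grandmother
non_patient	grandfather
non_patient	grandma
non_patient	grandpa
non_patient	mother in law
non_patient	motherinlaw
non_patient	father in law
non_patient	fatherinlaw
non_patient	daughter in law
non_patient	daughterinlaw
non_patient	son in law
non_patient	soninlaw
non_patient	sister in law
non_patient	sisterinlaw
non_patient	brother in law
non_patient	brotherinlaw
non_patient	friend
non_patient	neighbor
non_patient	roommate
non_patient	coworker
non_patient	family member
non_patient	family history
generic_instruction	return if
generic_instruction	call if
generic_instruction	call us if
generic_instruction	if you experience
generic_instruction	if you have
generic_instruction	if you develop
generic_instruction	if you notice
generic_instruction	seek care if
generic_instruction	seek medical attention if
generic_instruction	go to the emergency
generic_instruction	side effects
generic_instruction	side effect
generic_instruction	may cause
generic_instruction	can cause
generic_instruction	watch for
generic_instruction	warning signs
generic_instruction	notify us if
generic_instruction	please return
generic_instruction	return to ed
generic_instruction	return to the ed
checkbox_marker	yes
checkbox_marker	x
checkbox_marker	+
medication_indication	given for
medication_indication	prescribed for
medication_indication	taking for
medication_indication	takes for
medication_indication	to treat
medication_indication	for treatment of
medication_indication	to help with
medication_indication	to relieve
medication_indication	for relief of
medication_indication	medication for
present_report	i have
present_report	i am having
present_report	im having
present_report	i am experiencing
present_report	patient has
present_report	pt has
present_report	patient is
present_report	pt is
present_report	patient with
present_report	pt with
present_report	currently
present_report	has been having
present_report	have been having
scope_breaker	but
scope_breaker	however
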
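label	phrase
chief_complaint	chief complaint
diagnosis	diagnosis
diagnosis	diagnoses
diagnosis	primary encounter diagnosis
diagnosis	encounter diagnosis
diagnosis	assessment
symptom_list	symptoms
symptom_list	symptom list
symptom_list	symptom checklist
symptom_list	associated symptoms
history_present_illness	history of present illness
past_medical_history	past medical history
past_medical_history	past history
past_medical_history	medical history
family_history	family history
instructions	instructions
instructions	patient instructions
instructions	discharge instructions
instructions	return precautions
medications	medications
medications	current medications
medications	medication list
medications	meds
review_of_systems	review of systems
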
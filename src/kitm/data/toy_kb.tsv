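# kitm knowledge base	name=toy
[CONCEPTS]
T001	RXNORM_TOY	drug	drug|pharmaceutical product	drug
T002	RXNORM_TOY	antihypertensive agent	antihypertensive agent|antihypertensive	drug
T003	RXNORM_TOY	beta blocker	beta blocker|beta-blocker	drug
T004	RXNORM_TOY	atenolol	atenolol	drug
T005	RXNORM_TOY	angiotensin receptor blocker	angiotensin receptor blocker|arb	drug
T006	RXNORM_TOY	valsartan	valsartan|diovan	drug
T007	RXNORM_TOY	retinoid	retinoid	drug
T008	RXNORM_TOY	tazarotene	tazarotene|tazorac	drug
T009	RXNORM_TOY	antidepressant	antidepressant	drug
T010	RXNORM_TOY	trazodone	trazodone	drug
T011	RXNORM_TOY	bupropion	bupropion|wellbutrin	drug
T012	SNOMEDCT_TOY	condition	condition|clinical finding	condition
T013	SNOMEDCT_TOY	low libido	low libido|decreased libido	condition
T014	SNOMEDCT_TOY	grogginess	grogginess	condition
T015	SNOMEDCT_TOY	panic disorder	panic disorder	condition
T016	SNOMEDCT_TOY	smoking	smoking	condition
T017	SNOMEDCT_TOY	liver disorder	liver disorder	condition
T018	SNOMEDCT_TOY	cirrhotic ascites	cirrhotic ascites	condition
T019	SNOMEDCT_TOY	hypertension	hypertension|high blood pressure	condition
[RELATIONS]
T002	IS_A	T001
T003	IS_A	T002
T004	IS_A	T003
T005	IS_A	T002
T006	IS_A	T005
T007	IS_A	T001
T008	IS_A	T007
T009	IS_A	T001
T010	IS_A	T009
T011	IS_A	T009
T013	IS_A	T012
T014	IS_A	T012
T015	IS_A	T012
T016	IS_A	T012
T017	IS_A	T012
T018	IS_A	T017
T019	IS_A	T012
T004	may_cause	T013
T004	may_treat	T019
T006	may_treat	T019
T010	may_cause	T014
T011	may_treat	T016
T011	may_cause	T015
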
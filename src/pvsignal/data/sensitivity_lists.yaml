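# Editable default match lists for the sensitivity re-analyses.
#
# antidepressants: ATC N06A ingredients; antipsychotics: ATC N05A.
# pregnancy_indications: indication PTs describing pregnancy-related
# conditions or tocolysis / pregnancy-maintenance use.
antidepressants:
  - amitriptyline
  - bupropion
  - citalopram
  - clomipramine
  - desvenlafaxine
  - doxepin
  - duloxetine
  - escitalopram
  - fluoxetine
  - fluvoxamine
  - imipramine
  - mirtazapine
  - nortriptyline
  - paroxetine
  - sertraline
  - trazodone
  - venlafaxine
  - vortioxetine
antipsychotics:
  - aripiprazole
  - chlorpromazine
  - clozapine
  - haloperidol
  - lurasidone
  - olanzapine
  - paliperidone
  - quetiapine
  - risperidone
  - ziprasidone
pregnancy_indications:
  - Gestational hypertension
  - Pre-eclampsia
  - Preeclampsia
  - Eclampsia
  - Premature labour
  - Preterm labour
  - Tocolysis
  - Pregnancy
  - Maintenance of pregnancy
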
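# The 14 quantitative criteria of the EVIDEM framework, grouped into six
# categories. Category order and within-category order define the canonical
# leaf order used for every weight and score vector in this package.
criteria:
  - code: D1
    name: Disease severity
    category: Disease impact
    definition: >-
      Severity of the health condition targeted by the intervention with
      respect to mortality, disability, impact on quality of life and
      clinical course.
  - code: D2
    name: Size of population
    category: Disease impact
    definition: >-
      Number of people affected by the condition (incidence and/or
      prevalence) in a specified population.
  - code: I1
    name: Improvement of efficacy/effectiveness
    category: Intervention outcomes
    definition: >-
      Capacity to produce a beneficial change in signs, symptoms or course
      of the condition beyond alternative interventions.
  - code: I2
    name: Improvement of safety & tolerability
    category: Intervention outcomes
    definition: >-
      Reduction in harmful or undesired intervention-related health effects
      compared with alternatives.
  - code: I3
    name: Improvement of patient reported outcomes
    category: Intervention outcomes
    definition: >-
      Capacity to improve patient-reported outcomes (e.g. quality of life,
      convenience, adherence) beyond alternatives.
  - code: Q1
    name: Completeness and consistency of reporting evidence
    category: Quality of evidence
    definition: >-
      Extent to which reporting of evidence is complete and consistent with
      the sources cited.
  - code: Q2
    name: Relevance and validity of evidence
    category: Quality of evidence
    definition: >-
      Extent to which evidence is relevant to the decision-making body and
      scientifically valid, including consideration of uncertainty.
  - code: C1
    name: Clinical guidelines
    category: Context
    definition: >-
      Concurrence of the intervention with the current expert consensus on
      state-of-the-art management of the condition.
  - code: C2
    name: Comparative interventions limitations
    category: Context
    definition: >-
      Shortcomings of comparative interventions (unmet needs) in efficacy,
      safety, patient-reported outcomes or convenience.
  - code: T1
    name: Public health interest
    category: Type of benefit
    definition: >-
      Population-level risk reduction provided by the intervention
      (prevention, reduced transmission, reduced risk factors).
  - code: T2
    name: Type of medical service
    category: Type of benefit
    definition: >-
      Nature of the clinical benefit at the patient level (symptom relief,
      prolonging life, cure).
  - code: E1
    name: Budget impact on health plan
    category: Economics
    definition: >-
      Net impact of coverage on the health-plan budget, limited to the cost
      of the intervention itself.
  - code: E2
    name: Cost-effectiveness of intervention
    category: Economics
    definition: >-
      Ratio of incremental cost to incremental benefit compared with
      alternatives.
  - code: E3
    name: Impact on other spending
    category: Economics
    definition: >-
      Impact of coverage on expenditures other than the intervention cost
      (hospitalisation, disability, productivity, caregiver time).
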
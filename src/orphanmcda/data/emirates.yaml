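# Emirates MCDA criteria set for orphan-drug value assessment.
# Ten criteria; outcome-level scores in percent; ranking with a tie at rank 6;
# weight increases are percent importance over the next-ranked criterion
# (within the tied group, disease rarity carries 0% relative to clinical
# evidence; the lowest-ranked criterion's entry is carried but unused).
name: emirates-orphan-mcda
criteria:
  - id: cost_effectiveness
    name: Cost-effectiveness (Cost/QALY)
    category: economics-related
    levels:
      - {label: "Below 1x GDP per capita", score_percent: 100}
      - {label: "Between 1-2x GDP per capita", score_percent: 80}
      - {label: "Between 2-3x GDP per capita", score_percent: 60}
      - {label: "Between 3-5x GDP per capita", score_percent: 40}
      - {label: "Between 5-10x GDP per capita", score_percent: 20}
      - {label: "Above 10x GDP per capita", score_percent: 0}
  - id: magnitude_of_health_gain
    name: Magnitude of health gain
    category: treatment-related
    levels:
      - {label: "Curative therapy (no need for further therapy)", score_percent: 100}
      - {label: "Long-term remission on therapy (therapy until progression)", score_percent: 75}
      - {label: "Duration of benefits is 1-5 years", score_percent: 50}
      - {label: "Symptom relief or short-term benefit", score_percent: 0}
  - id: therapeutic_alternative
    name: Therapeutic alternative (unmet need)
    category: disease-related
    levels:
      - {label: "No effective treatments are available", score_percent: 100}
      - {label: "Less effective treatments are available", score_percent: 50}
      - {label: "Similarly effective treatments are available", score_percent: 0}
  - id: disease_severity
    name: Disease severity (expected QALYs without therapy)
    category: disease-related
    levels:
      - {label: "Chronic life threatening", score_percent: 100}
      - {label: "Acute life threatening", score_percent: 80}
      - {label: "Chronic with severe invalidity", score_percent: 60}
      - {label: "Acute with severe invalidity", score_percent: 40}
      - {label: "Other chronic diseases", score_percent: 20}
      - {label: "Other acute diseases", score_percent: 0}
  - id: budget_impact
    name: Budget impact
    category: economics-related
    levels:
      - {label: "Below 0.01% of annual drug budget", score_percent: 100}
      - {label: "Between 0.01-0.05% of annual drug budget", score_percent: 75}
      - {label: "Between 0.05-0.10% of annual drug budget", score_percent: 50}
      - {label: "Between 0.1-0.3% of annual drug budget", score_percent: 25}
      - {label: "Above 0.3% of annual drug budget", score_percent: 0}
  - id: disease_rarity
    name: Disease rarity
    category: disease-related
    levels:
      - {label: "Ultrarare disease", score_percent: 100}
      - {label: "Rare disease", score_percent: 50}
      - {label: "Rare subgroup of a common disease", score_percent: 0}
  - id: clinical_evidence
    name: Credibility and robustness of clinical evidence
    category: treatment-related
    levels:
      - {label: "Supportive RCT and real-world evidence", score_percent: 100}
      - {label: "Supportive RCT with at least 1 year follow-up", score_percent: 75}
      - {label: "Supportive RCT with <1 year follow-up", score_percent: 50}
      - {label: "Single arm phase 2 study", score_percent: 0}
  - id: household_burden
    name: Burden on households (patients & caregivers)
    category: disease-related
    levels:
      - {label: "Burden on patients or caregivers > direct medical cost", score_percent: 100}
      - {label: "Significant burden on patients or caregivers", score_percent: 75}
      - {label: "No evidence on household burden", score_percent: 0}
  - id: indication_uniqueness
    name: Indication uniqueness
    category: treatment-related
    levels:
      - {label: "One unique orphan indication", score_percent: 100}
      - {label: "Two orphan indications", score_percent: 50}
      - {label: "More than two orphan indications", score_percent: 25}
      - {label: "Non-orphan indications", score_percent: 0}
  - id: patient_age
    name: Average age of patients in clinical trials or real-world
    category: treatment-related
    levels:
      - {label: "Pediatrics (0-16 years)", score_percent: 100}
      - {label: "Young adults (17-30 years)", score_percent: 60}
      - {label: "Middle aged adults (31-65 years)", score_percent: 30}
      - {label: "Old age adults (above 65 years)", score_percent: 0}
ranking:
  - [cost_effectiveness]
  - [magnitude_of_health_gain]
  - [therapeutic_alternative]
  - [disease_severity]
  - [budget_impact]
  - [disease_rarity, clinical_evidence]
  - [household_burden]
  - [indication_uniqueness]
  - [patient_age]
increases:
  cost_effectiveness: 25.0
  magnitude_of_health_gain: 40.0
  therapeutic_alternative: 30.0
  disease_severity: 40.0
  budget_impact: 40.0
  disease_rarity: 0.0
  clinical_evidence: 25.0
  household_burden: 40.0
  indication_uniqueness: 25.0
  patient_age: 25.0
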
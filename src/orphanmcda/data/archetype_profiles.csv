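criterion,genetic curative therapy,highly effective chronic therapy,high-quality symptomatic therapy,lower-quality symptomatic therapy
cost_effectiveness,Between 3-5x GDP per capita,Between 5-10x GDP per capita,Between 1-2x GDP per capita,Between 5-10x GDP per capita
magnitude_of_health_gain,Curative therapy (no need for further therapy),Long-term remission on therapy (therapy until progression),Symptom relief or short-term benefit,Symptom relief or short-term benefit
therapeutic_alternative,No effective treatments are available,Less effective treatments are available,Less effective treatments are available,Similarly effective treatments are available
disease_severity,Chronic life threatening,Chronic with severe invalidity,Other chronic diseases,Other chronic diseases
budget_impact,Between 0.01-0.05% of annual drug budget,Between 0.05-0.10% of annual drug budget,Between 0.1-0.3% of annual drug budget,Above 0.3% of annual drug budget
disease_rarity,Ultrarare disease,Rare disease,Rare disease,Rare disease
clinical_evidence,Supportive RCT with <1 year follow-up,Supportive RCT and real-world evidence,Supportive RCT with at least 1 year follow-up,Single arm phase 2 study
household_burden,Burden on patients or caregivers > direct medical cost,Significant burden on patients or caregivers,No evidence on household burden,No evidence on household burden
indication_uniqueness,One unique orphan indication,One unique orphan indication,Two orphan indications,More than two orphan indications
patient_age,Pediatrics (0-16 years),Young adults (17-30 years),Middle aged adults (31-65 years),Middle aged adults (31-65 years)
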
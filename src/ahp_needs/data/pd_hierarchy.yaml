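# Decision hierarchy for user needs of a Parkinson's-disease telehealth system:
# 5 categories, 17 needs. Arrows in labels read "increase"/"decrease".
goal:
  id: pd_telehealth
  label: Telehealth system for Parkinson's disease monitoring, assessment and management
categories:
  - id: performance
    label: Performance
    needs:
      - id: motor_symptoms_assessment
        label: Motor symptoms assessment
      - id: on_off_fluctuations_detection
        label: ON/OFF fluctuations detection
      - id: cognitive_behavioral_assessment
        label: Cognitive & behavioral assessment
      - id: data_mining_disease_modelling
        label: Data mining & disease modelling
  - id: user_experience
    label: User experience
    needs:
      - id: increase_wearability_acceptance
        label: "↑ wearability acceptance"
      - id: user_friendly_interfaces
        label: User-friendly interfaces
      - id: seamlessly_integration
        label: Seamlessly integration
  - id: clinical_practice
    label: Clinical practice
    needs:
      - id: increase_patient_clinician_bond
        label: "↑ patient-clinician bond"
      - id: increase_patient_carers_knowledge
        label: "↑ patient & carers knowledge"
      - id: increase_self_management_support
        label: "↑ self-management support"
      - id: increase_assist_care_givers
        label: "↑ assist care givers"
  - id: economic
    label: Economic
    needs:
      - id: decrease_visits_and_stays_in_hospital
        label: "↓ visits and stays in hospital"
      - id: increase_patient_quality_of_life
        label: "↑ patient Quality of Life"
      - id: faster_and_more_reliable_diagnosis
        label: Faster and more reliable diagnosis
  - id: technical_issues
    label: Technical issues
    needs:
      - id: scalability_and_interoperability
        label: Scalability and interoperability
      - id: security_and_privacy
        label: Security and privacy
      - id: decrease_maintenance_and_support_cost
        label: "↓ maintenance and support cost"
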
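# Discharge-summary section schema: 27 canonical types.
# Definitions and example headings are authored reconstructions meant to be
# edited; they describe conventional discharge-summary structure, not any
# specific corpus.
name: discharge
types:
  - name: Admit date
    definition: the date of the patient's admit
    example_headings: ["ADMISSION DATE", "Admission Date", "DATE OF ADMISSION"]
  - name: Discharge date
    definition: the date the patient was discharged from the hospital
    example_headings: ["DISCHARGE DATE", "Discharge Date", "DATE OF DISCHARGE"]
  - name: Patient service
    definition: the hospital service or department that cared for the patient
    example_headings: ["SERVICE", "Service", "PATIENT SERVICE"]
  - name: Attending physician
    definition: the attending physician responsible for the patient's care
    example_headings: ["ATTENDING", "Attending Physician", "ATTENDING PHYSICIAN"]
  - name: Admitting physician
    definition: the physician who admitted the patient to the hospital
    example_headings: ["ADMITTING PHYSICIAN", "Admitting Physician"]
  - name: Reason for admission
    definition: the chief complaint or principal reason the patient was admitted
    example_headings: ["CHIEF COMPLAINT", "REASON FOR ADMISSION", "Reason for Admission"]
  - name: Admission diagnosis
    definition: the diagnosis established at the time of admission
    example_headings: ["ADMISSION DIAGNOSIS", "Admitting Diagnosis", "ADMITTING DIAGNOSIS"]
  - name: Discharge diagnosis
    definition: the final diagnosis at the time of discharge
    example_headings: ["DISCHARGE DIAGNOSIS", "Discharge Diagnosis", "FINAL DIAGNOSIS"]
  - name: Other diagnosis
    definition: secondary or additional diagnoses beyond the principal one
    example_headings: ["OTHER DIAGNOSES", "SECONDARY DIAGNOSES", "Other Diagnoses"]
  - name: History of present illness
    definition: the narrative of the current illness leading to this admission
    example_headings: ["HISTORY OF PRESENT ILLNESS", "History of Present Illness", "HPI"]
  - name: Past medical history
    definition: the patient's prior medical conditions and illnesses
    example_headings: ["PAST MEDICAL HISTORY", "Past Medical History", "PMH"]
  - name: Past surgical history
    definition: the patient's prior surgeries and operative procedures
    example_headings: ["PAST SURGICAL HISTORY", "Past Surgical History", "PSH"]
  - name: Gynecologic history
    definition: the patient's obstetric and gynecologic history
    example_headings: ["GYNECOLOGIC HISTORY", "OB/GYN HISTORY", "Gynecologic History"]
  - name: Social history
    definition: the patient's social circumstances such as tobacco, alcohol, and living situation
    example_headings: ["SOCIAL HISTORY", "Social History", "SH"]
  - name: Family history
    definition: medical conditions present in the patient's family
    example_headings: ["FAMILY HISTORY", "Family History", "FH"]
  - name: Allergies
    definition: the patient's drug and other allergies and reactions
    example_headings: ["ALLERGIES", "Allergies", "DRUG ALLERGIES"]
  - name: Admission medications
    definition: medications the patient was taking at the time of admission
    example_headings: ["MEDICATIONS ON ADMISSION", "ADMISSION MEDICATIONS", "Medications on Admission"]
  - name: Discharge medications
    definition: medications prescribed to the patient at discharge
    example_headings: ["DISCHARGE MEDICATIONS", "Discharge Medications", "MEDICATIONS ON DISCHARGE"]
  - name: Physical examination
    definition: findings from the physical examination of the patient
    example_headings: ["PHYSICAL EXAMINATION", "Physical Examination", "PHYSICAL EXAM"]
  - name: Lab studies
    definition: laboratory test results and other diagnostic study values
    example_headings: ["LABORATORY DATA", "LABS", "Laboratory Studies"]
  - name: Patient procedures
    definition: procedures and operations performed during this hospitalization
    example_headings: ["PROCEDURES", "Procedures Performed", "OPERATIONS AND PROCEDURES"]
  - name: Hospital course
    definition: the narrative of the patient's course during the hospital stay
    example_headings: ["HOSPITAL COURSE", "Hospital Course", "BRIEF HOSPITAL COURSE"]
  - name: Discharge condition
    definition: the patient's condition at the time of discharge
    example_headings: ["CONDITION ON DISCHARGE", "DISCHARGE CONDITION", "Condition at Discharge"]
  - name: Discharge instructions
    definition: instructions given to the patient for care after discharge
    example_headings: ["DISCHARGE INSTRUCTIONS", "Discharge Instructions", "INSTRUCTIONS"]
  - name: Follow-up
    definition: planned follow-up appointments and arrangements after discharge
    example_headings: ["FOLLOW-UP", "FOLLOW UP PLANS", "Follow-up Appointments"]
  - name: Patient comments
    definition: remarks about the patient's preferences, understanding, or statements
    example_headings: ["PATIENT COMMENTS", "Patient Comments"]
  - name: Unknown
    definition: a section whose content does not fit any of the defined section types
    example_headings: ["ADDENDUM", "NOTE", "MISCELLANEOUS"]
label_map:
  Physical: Physical examination
  Subsection: Unknown
  Addendum: Unknown
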
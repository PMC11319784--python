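# Progress-note (SOAP-style) section schema: 15 canonical types.
# Authored reconstruction of a conventional inpatient progress-note
# structure; definitions are editable starting points.
name: progress
types:
  - name: Chief complaint
    definition: the main problem or complaint the note addresses
    example_headings: ["CHIEF COMPLAINT", "CC", "Chief Complaint"]
  - name: History of present illness
    definition: the interval history and narrative of the current illness
    example_headings: ["HISTORY OF PRESENT ILLNESS", "HPI", "Interval History"]
  - name: Overnight events
    definition: events and changes in the patient's condition since the last note
    example_headings: ["OVERNIGHT EVENTS", "EVENTS", "Overnight Progress"]
  - name: Review of systems
    definition: the systematic review of symptoms by organ system
    example_headings: ["REVIEW OF SYSTEMS", "ROS", "Review of Systems"]
  - name: Vital signs
    definition: the patient's vital signs such as temperature, pulse, and blood pressure
    example_headings: ["VITAL SIGNS", "VITALS", "Vital Signs"]
  - name: Physical examination
    definition: findings from the physical examination of the patient
    example_headings: ["PHYSICAL EXAMINATION", "PHYSICAL EXAM", "PE"]
  - name: Lab studies
    definition: laboratory test results and other diagnostic study values
    example_headings: ["LABS", "LABORATORY DATA", "Lab Results"]
  - name: Imaging
    definition: results of imaging studies such as radiographs, CT, or MRI
    example_headings: ["IMAGING", "RADIOLOGY", "Imaging Studies"]
  - name: Medications
    definition: the patient's current medication list
    example_headings: ["MEDICATIONS", "CURRENT MEDICATIONS", "Meds"]
  - name: Allergies
    definition: the patient's drug and other allergies and reactions
    example_headings: ["ALLERGIES", "Allergies", "NKDA"]
  - name: Problem list
    definition: the enumerated list of active problems being followed
    example_headings: ["PROBLEM LIST", "ACTIVE PROBLEMS", "Problems"]
  - name: Assessment
    definition: the clinician's assessment and interpretation of the patient's status
    example_headings: ["ASSESSMENT", "IMPRESSION", "Assessment"]
  - name: Plan
    definition: the plan of care, including treatments and next steps
    example_headings: ["PLAN", "Plan", "ASSESSMENT AND PLAN"]
  - name: Code status
    definition: the patient's resuscitation preferences and code status
    example_headings: ["CODE STATUS", "CODE", "Code Status"]
  - name: Unknown
    definition: a section whose content does not fit any of the defined section types
    example_headings: ["ADDENDUM", "NOTE", "MISCELLANEOUS"]
label_map:
  Subjective: History of present illness
  Objective: Physical examination
  Subsection: Unknown
  Header: Unknown
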
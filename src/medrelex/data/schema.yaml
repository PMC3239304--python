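# Mini semantic schema: types -> categories, relation ranks, and the
# relations licensed per directed (source type, target type) pair.
types:
  - {name: Disease or Syndrome, category: Problem}
  - {name: Neoplastic Process, category: Problem}
  - {name: Anatomical Abnormality, category: Problem}
  - {name: Injury or Poisoning, category: Problem}
  - {name: Cell or Molecular Dysfunction, category: Problem}
  - {name: Sign or Symptom, category: Problem}
  - {name: Finding, category: Problem}
  - {name: Pharmacologic Substance, category: Treatment}
  - {name: Antibiotic, category: Treatment}
  - {name: Therapeutic or Preventive Procedure, category: Treatment}
  - {name: Diagnostic Procedure, category: Test}
  - {name: Laboratory Procedure, category: Test}
  - {name: Quantitative Concept, category: Other}
  - {name: Temporal Concept, category: Other}

# Trial order of candidate relations (lower rank tried first).
relations:
  - {name: treats, rank: 1}
  - {name: prevents, rank: 2}
  - {name: diagnoses, rank: 3}
  - {name: causes, rank: 4}
  - {name: sign_or_symptom_of, rank: 5}
  - {name: complicates, rank: 6}

licensed:
  - {source: Pharmacologic Substance, target: Disease or Syndrome,
     relations: [treats, prevents]}
  - {source: Pharmacologic Substance, target: Neoplastic Process,
     relations: [treats, prevents]}
  - {source: Pharmacologic Substance, target: Sign or Symptom,
     relations: [treats]}
  - {source: Antibiotic, target: Disease or Syndrome,
     relations: [treats, prevents]}
  - {source: Therapeutic or Preventive Procedure, target: Disease or Syndrome,
     relations: [treats, prevents, complicates, diagnoses, causes]}
  - {source: Therapeutic or Preventive Procedure, target: Neoplastic Process,
     relations: [treats, prevents]}
  - {source: Diagnostic Procedure, target: Disease or Syndrome,
     relations: [diagnoses]}
  - {source: Diagnostic Procedure, target: Neoplastic Process,
     relations: [diagnoses]}
  - {source: Laboratory Procedure, target: Disease or Syndrome,
     relations: [diagnoses]}
  - {source: Disease or Syndrome, target: Disease or Syndrome,
     relations: [causes, complicates]}
  - {source: Disease or Syndrome, target: Sign or Symptom,
     relations: [causes]}
  - {source: Neoplastic Process, target: Disease or Syndrome,
     relations: [causes, complicates]}
  - {source: Injury or Poisoning, target: Disease or Syndrome,
     relations: [causes]}
  - {source: Sign or Symptom, target: Disease or Syndrome,
     relations: [sign_or_symptom_of]}
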
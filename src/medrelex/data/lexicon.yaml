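# Starter lexicon: a small term -> concept dictionary with explicit
# surface variants.  Ids are CUI-like opaque strings; MX-prefixed ids are
# synthetic entries with no counterpart in any released vocabulary.
concepts:
  # --- treatments: pharmacologic substances -------------------------------
  - {id: C0003015, preferred_name: ACE inhibitors, semantic_types: [Pharmacologic Substance]}
  - {id: C0012798, preferred_name: Diazoxide, semantic_types: [Pharmacologic Substance]}
  - {id: C0016832, preferred_name: Fosfomycin, semantic_types: [Pharmacologic Substance]}
  - {id: C0052796, preferred_name: amoxicillin-clavulanate, semantic_types: [Pharmacologic Substance]}
  - {id: C0002645, preferred_name: Amoxicillin, semantic_types: [Pharmacologic Substance]}
  - {id: C0004057, preferred_name: aspirin, semantic_types: [Pharmacologic Substance]}
  - {id: C0025598, preferred_name: metformin, semantic_types: [Pharmacologic Substance]}
  - {id: C0043031, preferred_name: warfarin, semantic_types: [Pharmacologic Substance]}
  - {id: C0031469, preferred_name: Phenylephrine, semantic_types: [Pharmacologic Substance]}
  - {id: C0036442, preferred_name: Scopolamine, semantic_types: [Pharmacologic Substance]}
  - {id: C0039748, preferred_name: tetrahydrozoline, semantic_types: [Pharmacologic Substance]}
  - {id: C0022222, preferred_name: Ipratropium Bromide, semantic_types: [Pharmacologic Substance]}
  - {id: C0021641, preferred_name: insulin, semantic_types: [Pharmacologic Substance]}
  - {id: C0286651, preferred_name: atorvastatin, semantic_types: [Pharmacologic Substance]}
  - {id: C0020740, preferred_name: ibuprofen, semantic_types: [Pharmacologic Substance]}
  # --- treatments: antibiotics --------------------------------------------
  - {id: C0008809, preferred_name: ciprofloxacin, semantic_types: [Antibiotic]}
  - {id: C0028156, preferred_name: nitrofurantoin, semantic_types: [Antibiotic]}
  # --- treatments: procedures ---------------------------------------------
  - {id: C0013216, preferred_name: chemotherapy, semantic_types: [Therapeutic or Preventive Procedure]}
  - {id: C0034619, preferred_name: radiotherapy, semantic_types: [Therapeutic or Preventive Procedure]}
  - {id: C0003611, preferred_name: appendectomy, semantic_types: [Therapeutic or Preventive Procedure]}
  - {id: C0011946, preferred_name: dialysis, semantic_types: [Therapeutic or Preventive Procedure]}
  - {id: C0042196, preferred_name: vaccination, semantic_types: [Therapeutic or Preventive Procedure]}
  # --- problems: diseases --------------------------------------------------
  - {id: C0020538, preferred_name: hypertension, semantic_types: [Disease or Syndrome]}
  - {id: C0011849, preferred_name: diabetes, semantic_types: [Disease or Syndrome]}
  - {id: C0010692, preferred_name: cystitis, semantic_types: [Disease or Syndrome]}
  - {id: C0020615, preferred_name: hypoglycemia, semantic_types: [Disease or Syndrome]}
  - {id: C0004096, preferred_name: asthma, semantic_types: [Disease or Syndrome]}
  - {id: C0149931, preferred_name: migraine, semantic_types: [Disease or Syndrome]}
  - {id: C0042109, preferred_name: vasomotor rhinitis, semantic_types: [Disease or Syndrome]}
  - {id: C0032285, preferred_name: pneumonia, semantic_types: [Disease or Syndrome]}
  - {id: C0021400, preferred_name: influenza, semantic_types: [Disease or Syndrome]}
  - {id: C1615607, preferred_name: swine influenza, semantic_types: [Disease or Syndrome]}
  - {id: C0014544, preferred_name: epilepsy, semantic_types: [Disease or Syndrome]}
  - {id: C0002871, preferred_name: anemia, semantic_types: [Disease or Syndrome]}
  # synthetic: outcome phrase used in the segmentation worked example
  - {id: MX000001, preferred_name: cardiovascular disease outcomes, semantic_types: [Disease or Syndrome]}
  # --- problems: neoplasms -------------------------------------------------
  - {id: C0024299, preferred_name: lymphoma, semantic_types: [Neoplastic Process]}
  - {id: C0025202, preferred_name: melanoma, semantic_types: [Neoplastic Process]}
  - {id: C0023418, preferred_name: leukemia, semantic_types: [Neoplastic Process]}
  # --- problems: signs and symptoms ---------------------------------------
  - {id: C0015967, preferred_name: fever, semantic_types: [Sign or Symptom]}
  - {id: C0018681, preferred_name: headache, semantic_types: [Sign or Symptom]}
  - {id: C0027497, preferred_name: nausea, semantic_types: [Sign or Symptom]}
  - {id: C0010200, preferred_name: cough, semantic_types: [Sign or Symptom]}
  - {id: C0013404, preferred_name: dyspnea, semantic_types: [Sign or Symptom]}
  # --- problems: injuries, abnormalities, dysfunctions --------------------
  - {id: C0016658, preferred_name: fracture, semantic_types: [Injury or Poisoning]}
  - {id: C0032343, preferred_name: poisoning, semantic_types: [Injury or Poisoning]}
  - {id: C0016169, preferred_name: fistula, semantic_types: [Anatomical Abnormality]}
  - {id: C0002940, preferred_name: aneurysm, semantic_types: [Anatomical Abnormality]}
  - {id: C0334044, preferred_name: dysplasia, semantic_types: [Cell or Molecular Dysfunction]}
  # --- tests ---------------------------------------------------------------
  - {id: C0009378, preferred_name: colonoscopy, semantic_types: [Diagnostic Procedure]}
  - {id: C0005558, preferred_name: biopsy, semantic_types: [Diagnostic Procedure]}
  - {id: C0013516, preferred_name: echocardiography, semantic_types: [Diagnostic Procedure]}
  - {id: C0042014, preferred_name: urinalysis, semantic_types: [Laboratory Procedure]}
  - {id: C0200949, preferred_name: blood culture, semantic_types: [Laboratory Procedure]}
  # --- dictionary noise ----------------------------------------------------
  # synthetic: a general word that leaks into medical vocabularies; it is
  # both a term and a stoplist entry, and the stoplist wins at filter time
  - {id: MX000002, preferred_name: normal, semantic_types: [Finding]}
  - {id: C0178602, preferred_name: dose, semantic_types: [Quantitative Concept]}

terms:
  - {surface: angiotensin-converting enzyme inhibitors, concept_id: C0003015}
  - {surface: amoxycillin, concept_id: C0002645}
  - {surface: AMOX, concept_id: C0002645}
  - {surface: co-amoxiclav, concept_id: C0052796}
  - {surface: acetylsalicylic acid, concept_id: C0004057}
  - {surface: diabetes mellitus, concept_id: C0011849}
  - {surface: hypoglycaemia, concept_id: C0020615}
  - {surface: swine flu, concept_id: C1615607}
  - {surface: pig flu, concept_id: C1615607}
  - {surface: anaemia, concept_id: C0002871}
  - {surface: radiation therapy, concept_id: C0034619}
  - {surface: magnetic resonance imaging, concept_id: C0013516}

stoplist:
  - best
  - normal
  - take
  - reduce
  - give
  - show
  - use
  - make
  - place
  - time
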
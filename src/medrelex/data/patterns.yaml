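# Starter relation patterns.  E1/E2 slot categories default per relation
# (treats/prevents: Treatment->Problem; diagnoses: Test->Problem;
# causes/complicates/sign_or_symptom_of: Problem->Problem); "..." is a
# bounded gap of up to 6 tokens; "(...)?" groups are optional.
- {id: tr-effective-for, relation: treats,
   template: "E1 ... effective (for|against) E2"}
- {id: tr-found-to-reduce, relation: treats,
   template: "E1 was found to reduce E2"}
- {id: tr-used-to-treat, relation: treats,
   template: "E1 is used to treat E2"}
- {id: tr-treatment-for, relation: treats,
   template: "E1 is an effective treatment for E2"}
- {id: tr-relieves, relation: treats,
   template: "E1 relieves E2"}
- {id: pr-prophylaxis, relation: prevents,
   template: "E1 for prophylaxis against E2"}
- {id: pr-reduces-risk, relation: prevents,
   template: "E1 reduces the risk of E2"}
- {id: pr-prevents, relation: prevents,
   template: "E1 prevents ... E2"}
- {id: ca-may-trigger, relation: causes,
   template: "E1 may trigger E2"}
- {id: ca-leads-to, relation: causes,
   template: "E1 ... leads to E2"}
- {id: ca-induced-by, relation: causes,
   template: "E2 induced by E1"}
- {id: co-can-complicate, relation: complicates,
   template: "E1 can complicate ... E2"}
- {id: co-complicated-by, relation: complicates,
   template: "E2 (is|was) complicated by E1"}
- {id: di-best-test, relation: diagnoses,
   template: "E1 is the best test for (the diagnoses of)? E2"}
- {id: di-used-to-diagnose, relation: diagnoses,
   template: "E1 is used to diagnose E2"}
- {id: di-confirmed-by, relation: diagnoses,
   template: "E2 ... confirmed by E1"}
- {id: so-sign-of, relation: sign_or_symptom_of,
   template: "E1 is a (common)? sign of E2"}
- {id: so-symptom-of, relation: sign_or_symptom_of,
   template: "E1 ... symptom of E2"}
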
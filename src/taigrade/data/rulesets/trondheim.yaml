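# Trondheim TAI-MRI grading (grades 0-5; 0 = no TAI).
# Final grade = highest rule whose predicate holds.
# Posterior-limb internal-capsule lesions default to the grade-1 tier here;
# cerebellar peduncles count toward unilateral-brainstem grade 3 but do not
# trigger grades 4-5 without parenchymal mesencephalon/pons/medulla involvement.
# Bilateral medulla is not explicitly tiered by the grading's description;
# it defaults to grade 4 (bilateral non-pontine brainstem).
name: trondheim
no_tai_grade: 0
rules:
  - grade: 1
    predicate: >-
      tai_hemispheric or tai_cerebellum
      or tai_internal_capsule_pl_uni or tai_internal_capsule_pl_bil
  - grade: 2
    predicate: tai_corpus_callosum
  - grade: 3
    predicate: >-
      tai_thalamus_uni or tai_brainstem_uni
      or tai_cerebellar_peduncle_uni or tai_cerebellar_peduncle_bil
      or tai_basal_ganglia_uni or tai_basal_ganglia_bil
  - grade: 4
    predicate: tai_mesencephalon_bil or tai_thalamus_bil or tai_medulla_bil
  - grade: 5
    predicate: tai_pons_bil
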
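# Standard (Gentry/Adams) three-grade TAI grading.
# Grade 1: hemispheres (incl. cerebellum); grade 2: corpus callosum;
# grade 3: brainstem (incl. cerebellar peduncles). Deep grey structures
# (thalamus, basal ganglia, PL-IC) are not tiered by this grading and fall
# into the hemispheric tier. No-TAI patients receive grade 0.
name: standard
no_tai_grade: 0
rules:
  - grade: 1
    predicate: >-
      tai_hemispheric or tai_cerebellum
      or tai_internal_capsule_pl_uni or tai_internal_capsule_pl_bil
      or tai_basal_ganglia_uni or tai_basal_ganglia_bil
      or tai_thalamus_uni or tai_thalamus_bil
  - grade: 2
    predicate: tai_corpus_callosum
  - grade: 3
    predicate: >-
      tai_brainstem_any
      or tai_cerebellar_peduncle_uni or tai_cerebellar_peduncle_bil
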
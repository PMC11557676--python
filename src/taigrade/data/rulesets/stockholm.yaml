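# Stockholm MRI grading (APPROXIMATE reconstruction).
# Known anchors: thalamic TAI and bilateral pontine TAI are incorporated,
# bilateral pons is the worst grade, and patients without TAI share grade 1
# with hemispheric-only TAI. The intermediate tier composition is an
# approximation and should be reviewed against the original publication
# before any comparative claim.
name: stockholm
no_tai_grade: 1
rules:
  - grade: 1
    predicate: tai_hemispheric or tai_cerebellum
  - grade: 2
    predicate: >-
      tai_corpus_callosum
      or tai_internal_capsule_pl_uni or tai_internal_capsule_pl_bil
      or tai_basal_ganglia_uni or tai_basal_ganglia_bil
      or tai_thalamus_uni
  - grade: 3
    predicate: >-
      tai_brainstem_any
      or tai_cerebellar_peduncle_uni or tai_cerebellar_peduncle_bil
      or tai_thalamus_bil
  - grade: 4
    predicate: tai_pons_bil
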
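# TAI-MRI grading reflecting injury severity (GCS-based; APPROXIMATE
# reconstruction). Known anchor: bilateral TAI in the brainstem or thalami
# is the worst grade. Lower tiers mirror the standard grading with a deep
# unilateral tier inserted; review against the original publication before
# any comparative claim.
name: gcs_based
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
    predicate: tai_brainstem_bil or tai_thalamus_bil
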
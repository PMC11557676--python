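code,side,region_group,label
frontal_wm,left,hemispheric_wm,Frontal lobar white matter
frontal_wm,right,hemispheric_wm,Frontal lobar white matter
temporal_wm,left,hemispheric_wm,Temporal lobar white matter
temporal_wm,right,hemispheric_wm,Temporal lobar white matter
parietal_wm,left,hemispheric_wm,Parietal lobar white matter
parietal_wm,right,hemispheric_wm,Parietal lobar white matter
occipital_wm,left,hemispheric_wm,Occipital lobar white matter
occipital_wm,right,hemispheric_wm,Occipital lobar white matter
insular_wm,left,hemispheric_wm,Insular white matter
insular_wm,right,hemispheric_wm,Insular white matter
centrum_semiovale,left,hemispheric_wm,Centrum semiovale
centrum_semiovale,right,hemispheric_wm,Centrum semiovale
corona_radiata,left,hemispheric_wm,Corona radiata
corona_radiata,right,hemispheric_wm,Corona radiata
cingulum,left,hemispheric_wm,Cingulum
cingulum,right,hemispheric_wm,Cingulum
external_capsule,left,hemispheric_wm,External capsule
external_capsule,right,hemispheric_wm,External capsule
internal_capsule_al,left,hemispheric_wm,"Internal capsule, anterior limb"
internal_capsule_al,right,hemispheric_wm,"Internal capsule, anterior limb"
internal_capsule_pl,left,internal_capsule_pl,"Internal capsule, posterior limb"
internal_capsule_pl,right,internal_capsule_pl,"Internal capsule, posterior limb"
caudate,left,basal_ganglia,Caudate nucleus
caudate,right,basal_ganglia,Caudate nucleus
putamen,left,basal_ganglia,Putamen
putamen,right,basal_ganglia,Putamen
globus_pallidus,left,basal_ganglia,Globus pallidus
globus_pallidus,right,basal_ganglia,Globus pallidus
thalamus,left,thalamus,Thalamus
thalamus,right,thalamus,Thalamus
hippocampus,left,hemispheric_wm,Hippocampus
hippocampus,right,hemispheric_wm,Hippocampus
gray_white_junction,left,hemispheric_wm,Gray-white matter junction
gray_white_junction,right,hemispheric_wm,Gray-white matter junction
mesencephalon_crus_cerebri,left,mesencephalon,"Mesencephalon, crus cerebri"
mesencephalon_crus_cerebri,right,mesencephalon,"Mesencephalon, crus cerebri"
mesencephalon_tegmentum,left,mesencephalon,"Mesencephalon, tegmentum"
mesencephalon_tegmentum,right,mesencephalon,"Mesencephalon, tegmentum"
mesencephalon_tectum,left,mesencephalon,"Mesencephalon, tectum"
mesencephalon_tectum,right,mesencephalon,"Mesencephalon, tectum"
pons_ventral,left,pons,"Pons, ventral"
pons_ventral,right,pons,"Pons, ventral"
pons_tegmental,left,pons,"Pons, tegmental"
pons_tegmental,right,pons,"Pons, tegmental"
medulla,left,medulla,Medulla oblongata
medulla,right,medulla,Medulla oblongata
cerebellar_peduncle_superior,left,cerebellar_peduncle,Superior cerebellar peduncle
cerebellar_peduncle_superior,right,cerebellar_peduncle,Superior cerebellar peduncle
cerebellar_peduncle_middle,left,cerebellar_peduncle,Middle cerebellar peduncle
cerebellar_peduncle_middle,right,cerebellar_peduncle,Middle cerebellar peduncle
cerebellar_peduncle_inferior,left,cerebellar_peduncle,Inferior cerebellar peduncle
cerebellar_peduncle_inferior,right,cerebellar_peduncle,Inferior cerebellar peduncle
cerebellar_hemisphere,left,cerebellum,Cerebellar hemisphere
cerebellar_hemisphere,right,cerebellum,Cerebellar hemisphere
cc_genu,midline,corpus_callosum,"Corpus callosum, genu"
cc_truncus,midline,corpus_callosum,"Corpus callosum, truncus"
cc_splenium,midline,corpus_callosum,"Corpus callosum, splenium"
cerebellar_vermis,midline,cerebellum,Cerebellar vermis
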
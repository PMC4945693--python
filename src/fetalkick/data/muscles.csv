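# Planar 18-muscle lower-limb set.  Maximum isometric forces are adult
# reference values adapted from published adult lower-limb musculoskeletal
# datasets; they are deliberately NOT scaled when the skeleton is scaled.
# group: joint whose vicinity holds the muscle's origin (hip | knee).
name,group,fmax_n
psoas,hip,1113
iliacus,hip,1073
rectus_femoris,hip,1169
gluteus_medius,hip,1365
adductor_magnus,hip,1296
biceps_femoris_lh,hip,896
gluteus_maximus,hip,1500
piriformis,hip,296
gemelli,hip,164
gracilis,hip,162
sartorius,hip,156
semitendinosus,hip,410
soleus,knee,3549
tibialis_posterior,knee,1588
tibialis_anterior,knee,905
gastrocnemius_medialis,knee,1558
vastus_intermedius,knee,1365
vastus_lateralis,knee,1871
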
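# Planar (sagittal) muscle path points at adult scale.
# frac: fractional coordinate along the segment axis (proximal -> distal;
#       may be negative on the foot, whose axis runs ankle -> toes).
# offset_mm: perpendicular offset from the segment axis.  Sign convention
#   (canonical pose: femur/tibia vertical, toes anterior):
#   pelvis: positive = posterior;  femur/tibia: positive = anterior;
#   foot: positive = dorsal (up).
# Wrapping surfaces of 3D models are reduced to fixed via points.
name,seq,segment,frac,offset_mm
psoas,0,pelvis,0.50,-25
psoas,1,pelvis,0.02,-32
psoas,2,femur,0.12,-8
iliacus,0,pelvis,0.40,-28
iliacus,1,pelvis,0.02,-33
iliacus,2,femur,0.10,-7
rectus_femoris,0,pelvis,0.08,-40
rectus_femoris,1,femur,0.50,35
rectus_femoris,2,femur,0.97,42
rectus_femoris,3,tibia,0.08,35
gluteus_medius,0,pelvis,0.70,15
gluteus_medius,1,femur,0.04,0
adductor_magnus,0,pelvis,0.10,20
adductor_magnus,1,femur,0.45,-5
biceps_femoris_lh,0,pelvis,0.06,50
biceps_femoris_lh,1,tibia,0.08,-25
gluteus_maximus,0,pelvis,0.50,60
gluteus_maximus,1,femur,0.20,-30
piriformis,0,pelvis,0.30,40
piriformis,1,femur,0.03,-10
gemelli,0,pelvis,0.15,35
gemelli,1,femur,0.02,-12
gracilis,0,pelvis,0.05,-10
gracilis,1,tibia,0.12,-15
sartorius,0,pelvis,0.10,-42
sartorius,1,tibia,0.10,-18
semitendinosus,0,pelvis,0.07,52
semitendinosus,1,tibia,0.15,-35
soleus,0,tibia,0.20,-25
soleus,1,foot,-0.20,0
tibialis_posterior,0,tibia,0.30,-12
tibialis_posterior,1,tibia,0.98,-10
tibialis_posterior,2,foot,0.04,-9
tibialis_posterior,3,foot,0.25,-5
tibialis_anterior,0,tibia,0.25,18
tibialis_anterior,1,tibia,0.95,22
tibialis_anterior,2,foot,0.35,15
gastrocnemius_medialis,0,femur,0.93,-25
gastrocnemius_medialis,1,tibia,0.30,-35
gastrocnemius_medialis,2,foot,-0.20,0
vastus_intermedius,0,femur,0.30,25
vastus_intermedius,1,femur,0.97,42
vastus_intermedius,2,tibia,0.08,35
vastus_lateralis,0,femur,0.35,28
vastus_lateralis,1,femur,0.97,45
vastus_lateralis,2,tibia,0.08,36
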
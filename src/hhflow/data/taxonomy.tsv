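# hhflow action taxonomy: action_code <TAB> disposition <TAB> surface_category
# Dispositions: FLOW_PROCEDURE, FLOW_NEUTRAL, RECONTAMINATING_TOUCH, BREAKING,
# HYGIENE, SESSION_MARKER. surface_category applies to RECONTAMINATING_TOUCH
# only; "-" means not applicable. Users may extend this vocabulary; every code
# must carry exactly one disposition.
#
# Aseptic procedures of a delivery flow
wipe_vagina	FLOW_PROCEDURE	-
vaginal_exam	FLOW_PROCEDURE	-
rupture_membranes	FLOW_PROCEDURE	-
episiotomy	FLOW_PROCEDURE	-
catch_baby	FLOW_PROCEDURE	-
cord_cut_clamp	FLOW_PROCEDURE	-
cord_traction	FLOW_PROCEDURE	-
remove_placenta	FLOW_PROCEDURE	-
postdelivery_vaginal_exam	FLOW_PROCEDURE	-
suture_perineum	FLOW_PROCEDURE	-
wipe_baby	FLOW_PROCEDURE	-
urinary_catheter	FLOW_PROCEDURE	-
# Hand actions inside the patient zone (do not open a new opportunity)
touch_patient_zone	FLOW_NEUTRAL	-
touch_own_body	FLOW_NEUTRAL	-
touch_clean_delivery_surface	FLOW_NEUTRAL	-
touch_equipment_own_fluids	FLOW_NEUTRAL	-
touch_sterile_material	FLOW_NEUTRAL	-
give_injection	FLOW_NEUTRAL	-
support_breastfeeding	FLOW_NEUTRAL	-
carry_placenta	FLOW_NEUTRAL	-
# Hygiene actions
hand_rub	HYGIENE	-
hand_wash	HYGIENE	-
glove_don	HYGIENE	-
glove_remove	HYGIENE	-
hand_rinse_water	HYGIENE	-
# Touches on potentially contaminated surfaces (recontamination risk)
touch_glove_pack	RECONTAMINATING_TOUCH	glove_pack
touch_drying_material	RECONTAMINATING_TOUCH	unclean_drying_material
touch_patient_outside_zone	RECONTAMINATING_TOUCH	patient_outside_zone
touch_personal_bag	RECONTAMINATING_TOUCH	personal_bag
touch_unclean_delivery_surface	RECONTAMINATING_TOUCH	unclean_delivery_surface
touch_patient_bed	RECONTAMINATING_TOUCH	patient_bed
touch_waste_bin	RECONTAMINATING_TOUCH	waste_bin
touch_trolley	RECONTAMINATING_TOUCH	trolley
touch_hh_object	RECONTAMINATING_TOUCH	hh_object
touch_other_unclean	RECONTAMINATING_TOUCH	other_unclean
# Deliberate activities outside the workflow (break the delivery flow)
leave_room	BREAKING	-
blood_pressure	BREAKING	-
insert_iv_line	BREAKING	-
other_activity	BREAKING	-
# Session metadata markers (initial glove state noted by the observer)
session_start_bare	SESSION_MARKER	-
session_start_gloved	SESSION_MARKER	-
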
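item_code,unit_cost_gbp,unit_label,category,care_level
nicotine_patch,11,pack,pharmacotherapy,
nicotine_gum,11,pack,pharmacotherapy,
nicotine_tablet,16,pack,pharmacotherapy,
nicotine_inhalator,1,cartridge,pharmacotherapy,
nicotine_lozenge,14,pack,pharmacotherapy,
nicotine_nasal_spray,17,bottle,pharmacotherapy,
nicotine_mouth_spray,13,bottle,pharmacotherapy,
varenicline_2wk_initiation_pack,29,pack,pharmacotherapy,
varenicline_4wk_initiation_pack,55,pack,pharmacotherapy,
varenicline_0.5mg_tablet,0.98,tablet,pharmacotherapy,
varenicline_1mg_tablet,0.98,tablet,pharmacotherapy,
bupropion_150mg_tablet,0.70,tablet,pharmacotherapy,
bupropion_pack,41.76,pack,pharmacotherapy,
sss_group_session,1,session,cessation-advice,
sss_individual_session,9,session,cessation-advice,
gp_cessation_advice,38,session,cessation-advice,
practice_nurse_cessation_advice,8,session,cessation-advice,
pharmacist_cessation_advice,5,session,cessation-advice,
nhs_smoking_helpline_call,8,call,cessation-advice,
ae_attendance,113,attendance,healthcare,secondary
ae_admission,303,admission,healthcare,secondary
hospital_outpatient,165,appointment,healthcare,secondary
hospital_admission,2621,episode,healthcare,secondary
day_case,1038,case,healthcare,secondary
ambulance_convoy,390,convoy,healthcare,secondary
gp_consultation,38,consultation,healthcare,primary
practice_nurse_consultation,13,consultation,healthcare,primary
prescription,19,prescription,healthcare,primary
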
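# units: thousands
id,name,icer_usd_per_daly,cost_saving,cases_per_year,cost_full_usd,dalys_full,implementation_level,flags,icer_rank,low_confidence
mw38-male-circumcision,Male circumcision,22,False,4073,146730,39634,0.12,,38,False
mw04-isoniazid-preventive-therapy,Isoniazid preventive therapy for HIV+ no TB,1,False,55,80,1118,0.5,,4,False
mw05-first-line-treatment,First-line treatment for new TB cases for adults,3,False,14,178,1045,0.64,,5,False
mw07-first-line-treatment,First-line treatment for new TB cases for children,3,False,12,117,888,0.64,,7,False
mw09-clean-practices-and,Clean practices and immediate essential newborn care (home),3,False,671,416,237,0.0,,9,False
mw23-management-of-pre,Management of pre-eclampsia (magnesium sulfate),6,False,20,45,535,0.8,,23,False
mw41-voluntary-counselling-and,Voluntary counselling and testing,25,False,8031,36309,167,0.15,,41,False
mw22-rotavirus-vaccine,Rotavirus vaccine,6,False,651,3097,88,0.0,,22,False
mw33-households-owning-at,Households owning at least one ITN/LLIN,13,False,6752,13737,228,0.56,,33,False
mw19-malaria-treatment-first,Malaria treatment: first trimester-uncomplicated,5,False,305,1025,109,0.33,,19,False
mw27-pmtct-of-hiv,PMTCT of HIV,11,False,53,600,157,0.55,,27,False
mw13-malaria-treatment-uncomplicated,"Malaria treatment: uncomplicated-second line (adult, >36 kg)",4,False,4372,1186,59,0.02,,13,False
mw14-malaria-treatment-uncomplicated,"Malaria treatment: uncomplicated-second line (adult, <36 kg)",4,False,4372,593,59,0.04,,14,False
mw28-labour-and-delivery,Labour and delivery management,11,False,918,1281,170,0.65,,28,False
mw06-first-line-treatment,First-line treatment for retreatment TB cases for adults,3,False,2,100,131,0.65,,6,False
mw02-mass-media,Mass media,1,False,16879,7609,150,0.71,,2,False
mw11-malaria-treatment-uncomplicated,"Malaria treatment: uncomplicated (adult, <36 kg)",4,False,4372,3463,59,0.3,,11,False
mw48-interventions-focused-on,Interventions focused on men who have sex with men,51,False,34,1256,232,0.05,,48,False
mw36-antenatal-care-four,Antenatal care (four visits),15,False,918,11230,90,0.46,,36,False
mw08-first-line-treatment,First-line treatment for retreatment TB cases for children,3,False,2,66,111,0.65,,8,False
mw20-malaria-treatment-second,Malaria treatment: second trimester-uncomplicated,5,False,305,235,109,0.67,,20,False
mw40-antenatal-corticosteroids-for,Antenatal corticosteroids for preterm labour,25,False,165,406,47,0.0,,40,False
mw39-newborn-sepsis-full,Newborn sepsis - full supportive care,24,False,81,417,60,0.4,,39,False
mw01-cotrimoxazole-for-children,Cotrimoxazole for children,cost saving,True,127,220,0,0.13,,1,True
mw47-interventions-focused-on,Interventions focused on female sex workers,51,False,23,655,161,0.3,,47,False
mw31-vaginal-delivery-skilled,"Vaginal delivery, skilled attendance",12,False,918,5181,67,0.65,,31,False
mw12-malaria-treatment-uncomplicated,"Malaria treatment: uncomplicated (adult, >36 kg)",4,False,4372,4267,59,0.7,,12,False
mw24-tetanus-toxoid-pregnant,Tetanus toxoid (pregnant women),7,False,918,115,104,0.84,,24,False
mw17-malaria-treatment-uncomplicated,"Malaria treatment: uncomplicated-second line (children, <15 kg)",4,False,1042,35,14,0.02,,17,False
mw18-malaria-treatment-uncomplicated,"Malaria treatment: uncomplicated-second line (children, >15 kg)",4,False,1042,71,14,0.04,,18,False
mw42-schistosomiasis-mass-drug,Schistosomiasis mass drug administration,29,False,389,76.527,23.754,0.13,,42,False
mw25-vitamin-a-supplementation,Vitamin A supplementation in pregnant women,7,False,124,125,33,0.65,,25,False
mw16-malaria-treatment-uncomplicated,"Malaria treatment: uncomplicated (children, >15 kg)",4,False,1042,4768,14,0.4,,16,False
mw45-antibiotics-for-pprom,Antibiotics for pPRoM,40,False,64,39,30,0.3,,45,False
mw44-maternal-sepsis-case,Maternal sepsis case management,39,False,64,2731,20,0.0,,44,False
mw46-management-of-severe,Management of severe malnutrition (children),50,False,51,2437,199,0.8,,46,False
mw03-isoniazid-preventive-therapy,Isoniazid preventive therapy for children in contact with patients with TB,1,False,2,7,45,0.85,,3,False
mw15-malaria-treatment-uncomplicated,"Malaria treatment: uncomplicated (children, <15 kg)",4,False,1042,4576,14,0.6,,15,False
mw32-vaginal-delivery-with,"Vaginal delivery, with complication",12,False,138,804,10,0.51,,32,False
mw26-measles-vaccine,Measles vaccine,9,False,651,528,107,0.99,,26,False
mw30-management-of-obstructed,Management of obstructed labour,12,False,92,1100,2497,1.0,,30,False
mw43-caesarean-section,Caesarean section,32,False,34,672,327,1.0,,43,False
mw29-caesarean-section-with,Caesarean section (with complication),12,False,5,172,137,1.0,,29,False
mw34-pregnant-women-sleeping,Pregnant women sleeping under an ITN,13,False,1469,2990,50,1.0,,34,False
mw35-under-five-children,Under five children who slept under ITN/LLIN,13,False,494,1006,17,1.0,,35,False
mw37-blood-safety,Blood safety,15,False,40,1626,12,1.0,,37,False
mw21-malaria-treatment-pregnant,Malaria treatment: pregnant women - complicated,5,False,16,140,6,1.0,,21,False
mw10-case-management-of,Case management of MDR TB cases,3,False,0,12,5,1.0,,10,False
mw52-ipt-of-malaria,IPT of malaria (pregnant women),110,False,735,35,0,1.0,,52,False
mw63-git-tract-cancer,GIT tract cancer,804,False,0,3,0,0.5,,63,False
mw65-cervical-cancer-first,Cervical cancer (first line),1087,False,2,162,0,0.5,,65,False
mw61-ischaemic-heart-disease,Ischaemic heart disease,453,False,128,4,0,0.15,,61,False
mw57-diabetes-type-i,"Diabetes, type I",296,False,23,4304,0,0.15,,57,False
mw49-high-cholesterol,High cholesterol,68,False,223,6703,1,0.01,,49,False
mw50-basic-psychosocial-support,"Basic psychosocial support, advice and follow-up, plus antiepileptic medication",82,False,506,1266,1,0.03,,50,False
mw56-treatment-of-depression,Treatment of depression,265,False,169,332,0,0.01,,56,False
mw58-diabetes-type-ii,"Diabetes, Type II",296,False,138,4211,0,0.15,,58,False
mw66-treatment-of-acute,Treatment of acute psychotic disorders,1646,False,169,958,0,0.01,,66,False
mw62-treatment-of-bipolar,Treatment of bipolar disorder,557,False,523,10362,0,0.03,,62,False
mw67-treatment-of-schizophrenia,Treatment of schizophrenia,1646,False,2363,13413,0,0.14,,67,False
mw55-hypertension,Hypertension,159,False,846,1338,44,0.1,,55,False
mw54-ors,ORS,153,False,8662,937,147,0.69,,54,False
mw51-zinc-diarrhoea-treatment,Zinc (diarrhoea treatment),99,False,7455,1788,244,0.0,,51,False
mw53-condoms,Condoms,127,False,8031,22883,482,0.47,,53,False
mw59-art-for-men,ART for men,312,False,332,21159,1005,0.75,,59,False
mw60-art-for-women,ART for women,312,False,509,32440,1541,0.82,,60,False
mw64-paediatric-art,Paediatric ART,892,False,107,7657,1556,0.25,,64,False
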
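id,baseline,family,params,units,description,source
p_pregnancy,0.0654,beta,14.882;212.76,probability,Annual probability a woman becomes pregnant,national fertility data
p_hist_hysterectomy,0.017,beta,5378.14;310982.86,probability,Probability a woman has a history of hysterectomy at entry,population survey
p_hist_cs_national,0.172,beta,42994.32;206972.68,probability,Probability a woman has a history of CS (national),NFHS-4
p_hist_cs_rural,0.128,beta,23020.67;156828.33,probability,Probability a woman in a rural area has a history of CS,NFHS-4
p_hist_cs_urban,0.282,beta,19773.28;50344.72,probability,Probability a woman in an urban area has a history of CS,NFHS-4
p_access_national,0.502,beta,125483.43;124483.57,probability,Probability a woman has access to CEmOC (national),NFHS-4 + Gujarat facility data
p_access_rural,0.472,beta,84888.73;94960,probability,Probability a woman in a rural area has access to CEmOC,NFHS-4 + Gujarat facility data
p_access_urban,0.557,beta,39055.73;31062.27,probability,Probability a woman in an urban area has access to CEmOC,NFHS-4 + Gujarat facility data
p_antepartum_indication,0.0362,beta,893.49;23788.51,probability,Probability of an absolute indication for antepartum CS,literature
p_pph_vaginal,0.009,beta,1174.32;129305.68,probability,Probability of PPH in the setting of vaginal delivery,literature
p_hyst_vaginal,0.0003,beta,4.39;14632.61,probability,Probability of hysterectomy in the setting of vaginal delivery,literature
p_intrapartum_cs_tolac,0.739,beta,3346.93;1182.07,probability,Probability of intrapartum CS in the setting of TOLAC,literature
p_nonind_antepartum,0.0094,beta,42.98;4529.02,probability,Probability of a non-indicated antepartum CS (calibrated),model calibration
p_nonind_intrapartum_tolac,0.018,beta,21;1161,probability,Probability of a non-indicated intrapartum CS in the setting of TOLAC (calibrated),model calibration
p_pph_accreta,0.6,beta,18;12,probability,Probability of PPH in the setting of placenta accreta,literature
p_hyst_accreta,0.765,beta,42.84;13.16,probability,Probability of hysterectomy in the setting of placenta accreta,literature
p_pph_previa,0.2111,beta,57;213,probability,Probability of PPH in the setting of placenta previa,literature
p_rupture_tolac,0.0169,beta,25;1454,probability,Probability of uterine rupture in the setting of TOLAC,literature
p_hyst_rupture,0.0819,beta,14.61;163.75,probability,Probability of hysterectomy in the setting of uterine rupture during TOLAC,literature
p_icu_hysterectomy,0.357,beta,19.99;36.01,probability,Probability of ICU admission in the setting of a peripartum hysterectomy,literature
p_death_icu,0.2165,beta,42;152,probability,Probability of all-cause obstetric mortality during ICU admission,literature
p_intrapartum_indication,0.144,beta,3426;20348,probability,Probability of an absolute indication for intrapartum CS,literature
p_death_antepartum_indication,0.00323,beta,15.95;4920.62,probability,Probability of mortality in the setting of an absolute indication (placenta accreta or previa) for antepartum CS,literature
p_death_intrapartum_indication,0.0025,beta,15.96;6367.04,probability,Probability of mortality in the setting of an absolute indication (uterine rupture or obstructed labor) for intrapartum CS,literature
p_death_pph_vaginal,0.006,beta,11.01;18618.99,probability,Probability of mortality in the setting of PPH during vaginal delivery,literature
p_emergency_hyst_cs,0.0027,beta,39.52;14597.48,probability,Probability of emergency hysterectomy during CS,literature
p_pph_rupture,0.314,beta,50.55;110.45,probability,Probability of PPH in the setting of uterine rupture,literature
p_death_pph_no_access,0.0006,beta,11.01;18618.99,probability,Probability of mortality in the setting of PPH during vaginal delivery without access to care,literature
p_fistula,0.0001,beta,16;159967,probability,Probability of fistula following vaginal delivery with an unmet absolute indication for CS,literature
p_incontinence,0.0011,beta,15.98;14512.97,probability,Probability of incontinence during vaginal delivery with an unmet absolute indication for CS,literature
p_stroke,0.0015,beta,15.97;10633,probability,Probability of stroke during vaginal delivery with an unmet absolute indication for CS,literature
cost_vaginal,153.70,gamma,16;9.51,usd_2016,Cost of vaginal delivery at a facility,costing studies
cost_cs,745.66,gamma,16;47.93,usd_2016,Cost of cesarean section,costing studies
cost_pph,79.89,gamma,16;4.99,usd_2016,Cost of managing PPH including blood transfusion,costing studies
cost_hysterectomy,2241.42,gamma,16;140.09,usd_2016,Cost of peripartum hysterectomy,costing studies
cost_icu,1172.50,gamma,16;28.03,usd_2016,Cost of ICU admission,costing studies
u_pregnant,0.99,uniform,0.98;1.0,utility,Health-state utility while pregnant,GBD 2015
u_nonpregnant,1.0,point,1.0,utility,Health-state utility while non-pregnant,GBD 2015
u_hysterectomy,0.94,uniform,0.89;0.99,utility,Health-state utility with a history of hysterectomy,GBD 2015
u_dead,0.0,point,0.0,utility,Utility of the dead state,definition
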
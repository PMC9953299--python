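name,label,metabolite,value,unit,provenance
pregnancy_study,control,m1,85.6,pmol/L,"Pregnancy cohort, mean serum 1.25(OH)2D3 at 15 weeks, non-pregnant controls (n=9)"
pregnancy_study,pregnant,m1,336.3,pmol/L,"Pregnancy cohort, mean serum 1.25(OH)2D3 at 15 weeks, non-preeclamptic pregnant (n=25)"
pregnancy_study,preeclamptic,m1,388.8,pmol/L,"Pregnancy cohort, mean serum 1.25(OH)2D3 at 15 weeks, later-preeclamptic pregnant (n=25)"
pregnancy_study,control,m0,46.8,nmol/L,"Pregnancy cohort, mean serum 25(OH)D3, non-pregnant controls (n=9)"
pregnancy_study,pregnant,m0,44.7,nmol/L,"Pregnancy cohort, mean serum 25(OH)D3, non-preeclamptic pregnant (n=25)"
pregnancy_study,preeclamptic,m0,33.1,nmol/L,"Pregnancy cohort, mean serum 25(OH)D3, later-preeclamptic pregnant (n=25)"
pregnancy_study,control,m2,9.7,nmol/L,"Pregnancy cohort, mean serum 24.25(OH)2D3, non-pregnant controls (n=9)"
pregnancy_study,pregnant,m2,6.5,nmol/L,"Pregnancy cohort, mean serum 24.25(OH)2D3, non-preeclamptic pregnant (n=25)"
pregnancy_study,preeclamptic,m2,3.2,nmol/L,"Pregnancy cohort, mean serum 24.25(OH)2D3, later-preeclamptic pregnant (n=25)"
military_training,day_1,m0,61,ng/mL,"1993 US Army Special Forces selection course, mean serum 25(OH)D3, day 1 (range 34-100)"
military_training,day_10,m0,55,ng/mL,"1993 US Army Special Forces selection course, mean serum 25(OH)D3, day 10 (range 38-97)"
military_training,day_20,m0,51,ng/mL,"1993 US Army Special Forces selection course, mean serum 25(OH)D3, day 20 (range 42-60)"
diurnal_case,2017-10-11,m0,67,ng/mL,"2017 diurnal case study, midday serum 25(OH)D3, middle-aged woman on 5000 IU/day D3"
diurnal_case,2017-10-18,m0,65,ng/mL,"2017 diurnal case study, midday serum 25(OH)D3"
diurnal_case,2017-11-15,m0,51,ng/mL,"2017 diurnal case study, midday serum 25(OH)D3 during a brief cold"
diurnal_case,2017-11-28,m0,67,ng/mL,"2017 diurnal case study, midday serum 25(OH)D3 after recovery"
pregnancy_urine_m2,control,m2,55.4,nmol/L,"Pregnancy cohort, mean urine 24.25(OH)2D3, non-pregnant controls (n=9)"
pregnancy_urine_m2,pregnant,m2,84.1,nmol/L,"Pregnancy cohort, mean urine 24.25(OH)2D3, non-preeclamptic pregnant (n=25)"
pregnancy_urine_m2,preeclamptic,m2,35.6,nmol/L,"Pregnancy cohort, mean urine 24.25(OH)2D3, later-preeclamptic pregnant (n=25)"
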
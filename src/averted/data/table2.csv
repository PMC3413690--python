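intervention_id,name,current_coverage,sc1_target,sc1_averted,sc2_target,sc2_averted,sc3_target,sc3_averted,subcomponent_of
institutional_delivery,Institutional delivery,0.157,0.650,26700,0.900,45900,0.900,45900,
labor_delivery_management,Labor and delivery management,0.031,0.455,11800,0.900,21500,0.900,21500,institutional_delivery
ors,Oral Rehydration Solution,0.370,0.650,26700,0.900,42600,0.900,52800,
pneumonia_case_management,Case management of pneumonia,0.000,0.170,4200,0.900,20800,0.900,27000,
breastfeeding,Breastfeeding,0.490,0.570,2800,0.900,17600,0.900,18500,
neonatal_infection_management,Case management of severe neonatal infection,0.250,0.420,5800,0.900,15700,0.900,20200,
antimalarials,Antimalarials,0.080,0.540,8900,0.900,12600,0.080,0,
pneumococcal_vaccine,Pneumococcal vaccine,0.000,0.900,12600,0.900,12500,0.000,0,
zinc_treatment,Zinc for treatment,0.000,0.620,9900,0.900,12000,0.000,0,
itn_irs,Insecticide treated materials or indoor residual spraying,0.420,0.650,4200,0.900,8900,0.420,0,
postnatal_care,Preventive postnatal care,0.050,0.250,2300,0.900,8700,0.050,0,
kangaroo_mother_care,Kangaroo mother care,0.063,0.455,4800,0.900,8200,0.063,0,
pmtct,Prevention of Mother To Child Transmission of HIV (PMTCT),0.080,0.760,5700,0.900,7200,0.080,0,
water_source,Improved water source,0.652,0.983,5800,0.900,4400,0.900,0,
measles_vaccine,Measles vaccine,0.770,0.900,100,0.900,100,0.770,0,
total,Total,,,114600,,217200,,164400,
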
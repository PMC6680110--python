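# India Plus: fifteen nutrition-specific interventions from India's national
# policy framework, costed with local (Indian / South Asian) programme unit
# costs.  Unit-cost entries carry the raw basis (per day / per visit / per
# case) plus the published annual per-beneficiary value used for costing.

[scenario]
name = "india_plus"
description = "Nationally recommended nutrition-specific package (15 interventions, local unit costs)"

[currency]
inr_per_usd = 62.0
inflation_factor = 1.0

# ---------------------------------------------------------------- unit costs

[unit_costs.counselling_pregnancy]
amount = 0.43
currency = "USD"
basis = "per_visit"
visits_per_year = 4.1
printed_annual_usd = 1.76
source = "Face-to-face IYCF counselling costing, Bangladesh at-scale programme"

[unit_costs.counselling_breastfeeding]
amount = 0.11
currency = "USD"
basis = "per_visit"
visits_per_year = 15.2
printed_annual_usd = 1.67
source = "Face-to-face IYCF counselling costing, Bangladesh at-scale programme"

[unit_costs.counselling_cf_6_12m]
amount = 0.56
currency = "USD"
basis = "per_visit"
visits_per_year = 13.3
printed_annual_usd = 7.47
source = "Face-to-face IYCF counselling costing; published annual value kept (0.56 x 13.3 = 7.45 by our rounding path)"

[unit_costs.counselling_cf_12_24m]
amount = 0.23
currency = "USD"
basis = "per_visit"
visits_per_year = 12.2
printed_annual_usd = 2.80
source = "Face-to-face IYCF counselling costing, Bangladesh at-scale programme"

[unit_costs.complementary_food_child]
amount = 6.0
currency = "INR"
basis = "per_day"
days_per_year = 300
printed_annual_usd = 29.03
source = "ICDS supplementary nutrition cost norm, Rs 6/child-day, 300 feeding days"

[unit_costs.complementary_food_child_halfyear]
amount = 6.0
currency = "INR"
basis = "per_day"
days_per_year = 150
printed_annual_usd = 14.52
source = "ICDS child ration, 6-month entitlement (children 6-12 months)"

[unit_costs.supplementary_food_plw]
amount = 7.0
currency = "INR"
basis = "per_day"
days_per_year = 150
printed_annual_usd = 16.93
source = "ICDS ration for pregnant/lactating women, Rs 7/day for 6 months; published annual value kept (Rs 7 x 150 / 62.0 = 16.94 by our rounding path)"

[unit_costs.sam_food_ration]
amount = 9.0
currency = "INR"
basis = "per_day"
days_per_year = 90
printed_annual_usd = 13.06
source = "ICDS additional ration for severely underweight children, Rs 9/day for 3 months"

[unit_costs.ifa_pregnant]
amount = 0.72
currency = "USD"
basis = "per_beneficiary_year"
printed_annual_usd = 0.72
source = "National micronutrient investment plan; companion lactating-women rate 0.51 not separable in the published cost line"

[unit_costs.ifa_deworming_adolescents]
amount = 0.40
currency = "USD"
basis = "per_beneficiary_year"
printed_annual_usd = 0.40
source = "Adolescent anaemia control programme (weekly IFA + semi-annual deworming)"

[unit_costs.iron_children]
amount = 0.37
currency = "USD"
basis = "per_beneficiary_year"
printed_annual_usd = 0.37
source = "National micronutrient investment plan, child iron supplementation"

[unit_costs.vitamin_a]
amount = 0.07
currency = "USD"
basis = "per_beneficiary_year"
printed_annual_usd = 0.07
source = "National micronutrient investment plan, two supplementation rounds/yr"

[unit_costs.ors_zinc]
amount = 0.64
currency = "USD"
basis = "per_beneficiary_year"
printed_annual_usd = 0.64
source = "National rural health mission plan; 3 diarrhoea episodes/yr, 2 ORS sachets + 14 zinc days per episode folded into the annual rate"

[unit_costs.deworming_children]
amount = 0.23
currency = "USD"
basis = "per_beneficiary_year"
printed_annual_usd = 0.23
source = "National rural health mission plan, two deworming rounds/yr"

[unit_costs.sam_facility_treatment]
amount = 107.38
currency = "USD"
basis = "per_case"
printed_annual_usd = 107.38
source = "Facility-based SAM treatment operational guidelines, 12.5-day average stay"

[unit_costs.itn]
amount = 4.84
currency = "USD"
basis = "per_beneficiary_year"
printed_annual_usd = 4.84
source = "Insecticide-treated bed net, procurement + delivery"

[unit_costs.cash_transfer]
amount = 103.22
currency = "USD"
basis = "per_beneficiary_year"
printed_annual_usd = 103.22
source = "Maternity benefit (6-month conditional cash transfer), benefit + incentives"

# -------------------------------------------------------------- interventions

[intervention.counselling_pregnancy]
name = "Counselling during pregnancy"
category = "counselling"
unit_cost = "counselling_pregnancy"
[intervention.counselling_pregnancy.target]
cohort = "pregnant_women"

[intervention.counselling_breastfeeding]
name = "Counselling for breastfeeding"
category = "counselling"
unit_cost = "counselling_breastfeeding"
[intervention.counselling_breastfeeding.target]
cohort = "children_0_6m"

[intervention.counselling_cf_handwashing]
name = "Counselling for complementary feeding and hand washing"
category = "counselling"
unit_cost = "counselling_cf_6_12m"
[intervention.counselling_cf_handwashing.target]
cohort = "children_6_23m"

[intervention.complementary_food]
name = "Complementary food supplements for children 6-36 months of age"
category = "supplementation"
unit_cost = "complementary_food_child"
[intervention.complementary_food.target]
cohort = "children_6_36m"

[intervention.supplementary_food_plw]
name = "Supplementary food rations for pregnant and lactating women"
category = "supplementation"
unit_cost = "supplementary_food_plw"
[intervention.supplementary_food_plw.target]
cohort = "pregnant_women"

[intervention.food_rations_sam]
name = "Additional food rations for severely malnourished children"
category = "supplementation"
unit_cost = "sam_food_ration"
[intervention.food_rations_sam.target]
cohort = "children_6_59m"
[intervention.food_rations_sam.target.prevalence_filter]
indicator = "waz_lt_m3"

[intervention.ifa_pregnant_lactating]
name = "Iron-folic acid supplements for pregnant and breastfeeding women"
category = "micronutrient_deworming"
unit_cost = "ifa_pregnant"
[intervention.ifa_pregnant_lactating.target]
cohort = "pregnant_women"

[intervention.ifa_deworming_adolescents]
name = "IFA supplements and deworming for adolescents"
category = "micronutrient_deworming"
unit_cost = "ifa_deworming_adolescents"
[intervention.ifa_deworming_adolescents.target]
cohort = "adolescents_11_18y"

[intervention.iron_supplements_children]
name = "Iron supplements for children 6-36 months of age"
category = "micronutrient_deworming"
unit_cost = "iron_children"
[intervention.iron_supplements_children.target]
cohort = "children_6_59m"

[intervention.vitamin_a]
name = "Vitamin A supplementation"
category = "micronutrient_deworming"
unit_cost = "vitamin_a"
[intervention.vitamin_a.target]
cohort = "children_6_59m"

[intervention.ors_zinc]
name = "ORS and therapeutic zinc supplements for treatment of diarrhoea"
category = "micronutrient_deworming"
unit_cost = "ors_zinc"
[intervention.ors_zinc.target]
cohort = "children_2_59m"

[intervention.deworming_children]
name = "Deworming"
category = "micronutrient_deworming"
unit_cost = "deworming_children"
[intervention.deworming_children.target]
cohort = "children_12_59m"

[intervention.sam_treatment]
name = "Treatment of severe acute malnutrition"
category = "health"
unit_cost = "sam_facility_treatment"
coverage = 1.0
[intervention.sam_treatment.target]
cohort = "children_6_59m"
incidence_multiplier = 2.0
inpatient_fraction = 0.15
[intervention.sam_treatment.target.prevalence_filter]
indicator = "whz_lt_m3"

[intervention.itn_pregnant]
name = "Insecticide treated nets for pregnant women in malaria-endemic areas"
category = "health"
unit_cost = "itn"
[intervention.itn_pregnant.target]
cohort = "pregnant_women"
endemic_only = true

[intervention.cash_transfers]
name = "Cash transfers to women in the first 6 months after delivery"
category = "cash_transfer"
unit_cost = "cash_transfer"
[intervention.cash_transfers.target]
cohort = "lactating_mothers_0_6m"
exclude_govt_employed = true
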
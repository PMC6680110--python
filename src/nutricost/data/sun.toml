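# SUN: the ten-intervention Scaling Up Nutrition global costing package
# applied to India, with the global (SUNWWIC) unit costs and India-specific
# target populations.  Category labels follow the published comparison-figure
# groupings.

[scenario]
name = "sun"
description = "Scaling Up Nutrition 10-intervention package with global unit costs"

[currency]
inr_per_usd = 62.0
inflation_factor = 1.0

# ---------------------------------------------------------------- unit costs

[unit_costs.bcc_household]
amount = 15.00
currency = "USD"
basis = "per_household_year"
children_per_household = 2
printed_annual_usd = 7.50
source = "Community nutrition BCC, $15/household-yr; two under-fives assumed per household"

[unit_costs.vitamin_a_sun]
amount = 1.20
currency = "USD"
basis = "per_beneficiary_year"
printed_annual_usd = 1.20
source = "Global package rate, two doses/yr"

[unit_costs.zinc_sun]
amount = 1.00
currency = "USD"
basis = "per_beneficiary_year"
printed_annual_usd = 1.00
source = "Global package rate, two to three supplementation rounds/yr"

[unit_costs.mnp]
amount = 3.60
currency = "USD"
basis = "per_beneficiary_year"
printed_annual_usd = 3.60
source = "Multiple micronutrient powders, 60 sachets per child"

[unit_costs.deworming_sun]
amount = 0.50
currency = "USD"
basis = "per_beneficiary_year"
printed_annual_usd = 0.50
source = "Global package rate, two rounds/yr"

[unit_costs.ifa_pregnancy_sun]
amount = 2.00
currency = "USD"
basis = "per_pregnancy"
printed_annual_usd = 2.00
source = "IFA for the last two trimesters of pregnancy"

[unit_costs.iron_fortification]
amount = 0.20
currency = "USD"
basis = "per_beneficiary_year"
printed_annual_usd = 0.20
source = "Iron fortification of staple foods, general population"

[unit_costs.salt_iodization]
amount = 0.05
currency = "USD"
basis = "per_beneficiary_year"
printed_annual_usd = 0.05
source = "Salt iodization, general population"

[unit_costs.complementary_food_sun]
amount = 51.10
currency = "USD"
basis = "per_beneficiary_year"
printed_annual_usd = 51.10
source = "Complementary food ~250 kcal/day ($0.13/child-day ready-to-use food)"

[unit_costs.cmam]
amount = 200.00
currency = "USD"
basis = "per_case"
printed_annual_usd = 200.00
source = "Community-based management of acute malnutrition, per child treated"

# -------------------------------------------------------------- interventions

[intervention.bcc]
name = "Community nutrition programmes for behaviour change communication"
category = "counselling"
unit_cost = "bcc_household"
[intervention.bcc.target]
cohort = "children_0_59m"

[intervention.vitamin_a_sun]
name = "Vitamin A supplementation"
category = "micronutrient_deworming"
unit_cost = "vitamin_a_sun"
[intervention.vitamin_a_sun.target]
cohort = "children_6_59m"

[intervention.zinc_sun]
name = "Zinc supplementation"
category = "micronutrient_deworming"
unit_cost = "zinc_sun"
[intervention.zinc_sun.target]
cohort = "children_6_59m"

[intervention.mnp]
name = "Multiple micronutrient powders"
category = "micronutrient_deworming"
unit_cost = "mnp"
[intervention.mnp.target]
cohort = "children_6_23m"
subtract_rule = "complementary_food_sun"

[intervention.deworming_sun]
name = "Deworming"
category = "micronutrient_deworming"
unit_cost = "deworming_sun"
[intervention.deworming_sun.target]
cohort = "children_12_59m"

[intervention.ifa_pregnant_sun]
name = "IFA supplements"
category = "micronutrient_deworming"
unit_cost = "ifa_pregnancy_sun"
[intervention.ifa_pregnant_sun.target]
cohort = "pregnant_women"

[intervention.iron_fortification]
name = "Iron fortification of staple foods"
category = "fortification"
unit_cost = "iron_fortification"
[intervention.iron_fortification.target]
cohort = "general_population"

[intervention.salt_iodization]
name = "Salt iodization"
category = "fortification"
unit_cost = "salt_iodization"
[intervention.salt_iodization.target]
cohort = "general_population"

[intervention.complementary_food_sun]
name = "Complementary food for prevention or treatment of moderate malnutrition"
category = "supplementation"
unit_cost = "complementary_food_sun"
[intervention.complementary_food_sun.target]
cohort = "children_6_23m"
[intervention.complementary_food_sun.target.prevalence_filter]
indicator = "whz_lt_m2"
multiplier = 2.0

[intervention.cmam]
name = "Treatment of SAM using community-based management of acute malnutrition"
category = "health"
unit_cost = "cmam"
[intervention.cmam.target]
cohort = "children_6_59m"
incidence_multiplier = 2.0
expected_reduction = 0.5
exclusion_fraction = 0.2
[intervention.cmam.target.prevalence_filter]
indicator = "whz_lt_m3"
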
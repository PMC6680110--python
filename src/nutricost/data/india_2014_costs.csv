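scenario,intervention_id,cost_usd_million,provenance
india_plus,counselling_pregnancy,49.61,national cost table (India Plus package)
india_plus,counselling_breastfeeding,17.87,national cost table (India Plus package)
india_plus,counselling_cf_handwashing,219.56,national cost table (India Plus package)
india_plus,complementary_food,1526.01,national cost table (India Plus package)
india_plus,supplementary_food_plw,658.35,national cost table (India Plus package)
india_plus,food_rations_sam,111.04,national cost table (India Plus package)
india_plus,ifa_pregnant_lactating,19.83,national cost table (India Plus package)
india_plus,ifa_deworming_adolescents,40.19,national cost table (India Plus package)
india_plus,iron_supplements_children,40.02,national cost table (India Plus package)
india_plus,vitamin_a,7.57,national cost table (India Plus package)
india_plus,ors_zinc,70.99,national cost table (India Plus package)
india_plus,deworming_children,22.41,national cost table (India Plus package)
india_plus,sam_treatment,222.98,national cost table (India Plus package)
india_plus,itn_pregnant,24.76,national cost table (India Plus package)
india_plus,cash_transfers,2899.73,national cost table (India Plus package)
sun,bcc,891.42,national cost table (SUN package)
sun,vitamin_a_sun,129.79,national cost table (SUN package)
sun,zinc_sun,5.54,national cost table (SUN package)
sun,mnp,4.84,national cost table (SUN package)
sun,deworming_sun,59.43,national cost table (SUN package)
sun,ifa_pregnant_sun,56.37,national cost table (SUN package)
sun,iron_fortification,255.07,national cost table (SUN package)
sun,salt_iodization,63.77,national cost table (SUN package)
sun,complementary_food_sun,1649.40,national cost table (SUN package)
sun,cmam,1107.51,national cost table (SUN package)
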
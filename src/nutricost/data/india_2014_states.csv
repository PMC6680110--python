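region_id,region_group,is_subtotal,total_population_million,counselling_usd_million,supplementation_usd_million,micronutrient_deworming_usd_million,health_usd_million,cash_transfer_usd_million,malaria_endemic
indo_gangetic_plains,indo_gangetic_plains,True,427.7,108.3,903.9,90.6,102.1,1197.1,False
uttar_pradesh,indo_gangetic_plains,False,199.6,51.4,420.8,42.7,32.5,616.9,False
bihar,indo_gangetic_plains,False,103.8,30.1,266.5,25.5,33.9,324.0,False
west_bengal,indo_gangetic_plains,False,91.3,17.7,140.7,15.0,17.8,164.2,True
jharkhand,indo_gangetic_plains,False,33.0,9.0,75.8,7.4,17.9,91.9,True
central_states,central_states,True,252.5,60.8,475.2,46.7,62.0,587.1,False
madhya_pradesh,central_states,False,72.6,20.1,162.4,15.3,29.2,216.8,False
maharashtra,central_states,False,112.4,24.3,186.2,18.7,14.9,207.2,False
chhattisgarh,central_states,False,25.5,6.9,52.8,5.2,7.8,70.9,True
odisha,central_states,False,41.9,9.5,73.8,7.4,10.1,92.2,True
western,western,True,182.1,45.3,356.9,35.1,31.4,454.8,False
rajasthan,western,False,68.6,19.2,152.6,14.9,16.6,200.6,False
gujarat,western,False,60.4,14.0,113.8,11.1,9.8,143.3,False
haryana,western,False,25.4,6.5,49.0,4.8,3.6,61.6,False
punjab,western,False,27.7,5.6,41.6,4.3,1.4,49.3,False
southern,southern,True,252.8,50.0,375.7,38.8,33.2,464.5,False
andhra_pradesh,southern,False,84.7,16.6,123.1,12.9,6.6,160.5,False
karnataka,southern,False,61.1,13.1,101.7,10.2,9.1,126.8,False
tamil_nadu,southern,False,72.1,13.8,103.1,10.7,14.3,123.8,False
kerala,southern,False,33.4,6.3,45.7,4.8,3.0,51.3,False
goa,southern,False,1.5,0.3,2.0,0.2,0.2,2.0,False
northern,northern,True,29.5,7.4,56.2,5.8,4.5,58.8,False
jammu_and_kashmir,northern,False,12.5,3.6,26.9,2.8,1.9,25.2,False
uttaranchal,northern,False,10.1,2.4,18.4,1.9,1.5,21.3,False
himachal_pradesh,northern,False,6.9,1.4,10.9,1.1,1.1,12.3,False
north_eastern,north_eastern,True,44.5,11.2,90.0,9.1,13.1,104.2,False
meghalaya,north_eastern,False,3.0,1.1,8.6,0.8,2.9,8.0,True
tripura,north_eastern,False,3.7,0.8,6.1,0.6,1.1,5.9,True
manipur,north_eastern,False,2.7,0.6,4.5,0.5,0.4,4.4,True
nagaland,north_eastern,False,2.0,0.4,3.5,0.4,0.5,3.4,True
arunachal_pradesh,north_eastern,False,1.4,0.3,2.9,0.3,0.4,3.1,True
assam,north_eastern,False,31.2,7.9,63.7,6.4,7.7,78.2,True
sikkim,north_eastern,False,0.6,0.1,0.8,0.1,0.1,1.1,False
union_territories,union_territories,True,21.2,4.6,35.3,3.6,3.8,41.0,False
delhi,union_territories,False,16.8,3.6,27.4,2.8,3.0,32.5,False
puducherry,union_territories,False,1.2,0.3,2.0,0.2,0.2,2.3,False
mizoram,union_territories,False,1.1,0.3,2.4,0.2,0.2,2.0,True
chandigarh,union_territories,False,1.1,0.2,1.6,0.2,0.2,1.8,False
dadra_and_nagar_haveli,union_territories,False,0.3,0.1,0.9,0.1,0.1,1.1,False
andaman_and_nicobar_islands,union_territories,False,0.4,0.1,0.6,0.1,0.1,0.6,True
daman_and_diu,union_territories,False,0.2,0.1,0.4,0.0,0.0,0.5,False
lakshadweep,union_territories,False,0.1,0.0,0.1,0.0,0.0,0.1,False
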
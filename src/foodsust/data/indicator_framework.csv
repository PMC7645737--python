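id,label,dimension,activity
access_to_land,Access to land by food system actors,food_security,production
access_to_water_production,Access to water for production,food_security,production
capacity_to_process_food,Capacity in the food system to process food,food_security,processing_storage
capacity_to_store_food,Capacity to store food,food_security,retail_trade
food_affordability,Availability of food at affordable prices,food_security,consumption
share_local_food,Share of locally produced food in the food system,food_security,consumption
ability_to_provide_food,Ability to provide food to food system actors,food_security,consumption
good_diet_perception,Capacity of the food system to fulfil the perceptions of local families of a good diet,food_security,consumption
household_food_security,Household food security level,food_security,transversal
water_accessibility_domestic,Water accessibility for domestic consumption,right_to_food,production
water_quality_domestic,Water quality for domestic consumption,right_to_food,production
water_accessibility_irrigation,Food system impact on overall water accessibility for irrigation,right_to_food,production
access_to_seeds,Access to seeds,right_to_food,production
land_tenure_perceptions,Perceptions on land tenure and land rights,right_to_food,production
women_land_rights,Proportion of women with land rights (access use and tenure of land),right_to_food,production
women_access_credit,Proportion of women who have access to agricultural credit,right_to_food,production
contribution_food_diversity,Contribution to food diversity,right_to_food,consumption
covering_nutritional_needs,Covering nutritional needs,right_to_food,consumption
local_food_traditions,Promotion of local food traditions,right_to_food,consumption
access_food_information,Perception on access to food-related information,right_to_food,consumption
participation_decision_making,Perception on participation in decision-making related to food,right_to_food,consumption
remedies_right_to_food,Remedies for violations of the right to food,right_to_food,transversal
child_labour,Child labour (proportion of school-age children not engaged in work in the food system),right_to_food,transversal
farmers_incomes,Farmers' incomes,poverty_inequality,production
wages_large_farm,Wages of large-farm employees,poverty_inequality,production
wages_processing_storage,Wages of employees at processing and storage levels,poverty_inequality,processing_storage
wages_retail,Wages of employees at retail level,poverty_inequality,retail_trade
food_expenditure,Food expenditure and consumption baskets (including non-marketed production),poverty_inequality,consumption
financial_capital,Financial capital (savings income access to finance),poverty_inequality,transversal
human_capital,Human capital (education experience health),poverty_inequality,transversal
social_capital,Social capital: membership or participation in networks and mutual support,poverty_inequality,transversal
physical_capital,Physical capital (infrastructure fulfilment of basic needs transport storage livestock),poverty_inequality,transversal
natural_capital,Natural capital: quantity and quality of households' natural resources,poverty_inequality,production
working_conditions,Decent and safe working conditions,poverty_inequality,transversal
social_protection,Social protection: access to social security health care and income security,poverty_inequality,transversal
agroecosystem_service_capacity,Agroecosystem service capacity,environmental_performance,production
soil_quality,Soil quality,environmental_performance,production
use_of_agrochemicals,Use of agrochemicals,environmental_performance,production
use_of_materials,Use of materials (plastics and others),environmental_performance,transversal
energy_use,Energy use intensity,environmental_performance,transversal
carbon_footprint,Carbon footprint,environmental_performance,transversal
water_footprint,Water footprint,environmental_performance,transversal
health_impact_perceptions,Health impact perceptions related to the food system,environmental_performance,transversal
diversity_crops_breeds,Diversity of crops and breeds,social_ecological_resilience,production
landscape_heterogeneity,Landscape heterogeneity,social_ecological_resilience,production
liveable_wage,Liveable wage,social_ecological_resilience,transversal
decentralization_independence,Decentralization and independence,social_ecological_resilience,transversal
local_consumption_production,Local consumption of production (proportion of food produced and consumed locally or on-farm),social_ecological_resilience,consumption
interest_groups,Organization in interest groups,social_ecological_resilience,transversal
ecological_self_regulation,Ecological self-regulation (provision of habitats for biodiversity),social_ecological_resilience,production
connectivity,Connectivity of food systems and their components,social_ecological_resilience,transversal
knowledge_threats_opportunities,Knowledge of threats and opportunities,social_ecological_resilience,transversal
reflective_shared_learning,Reflective and shared learning,social_ecological_resilience,transversal
feedback_mechanisms,Functioning feedback mechanisms,social_ecological_resilience,transversal
knowledge_legacy_identity,Knowledge legacy and identity,social_ecological_resilience,transversal
shared_vision,Shared vision on the food system,social_ecological_resilience,transversal
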
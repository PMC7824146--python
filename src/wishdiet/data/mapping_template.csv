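food_item,component_id
brown rice,whole_grains
whole wheat bread,whole_grains
morning glory,vegetables
cabbage,vegetables
banana,fruits
mango,fruits
fresh milk,dairy
yoghurt,dairy
beef,red_meat
pork,red_meat
tilapia,fish
shrimp,fish
chicken egg,eggs
duck egg,eggs
chicken meat,poultry
duck meat,poultry
tofu,legumes
mung beans,legumes
peanuts,nuts
cashews,nuts
soybean oil,unsat_oils
sunflower oil,unsat_oils
palm oil,sat_oils
lard,sat_oils
table sugar,added_sugars
soft drink,added_sugars
white rice,EXCLUDED
potato,EXCLUDED
fruit juice,EXCLUDED
pickled vegetables,EXCLUDED
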
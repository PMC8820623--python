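product_id,name,group
oat,Oat,GRAINS_ROOTS_TUBERS
barley,Barley,GRAINS_ROOTS_TUBERS
wheat,Wheat,GRAINS_ROOTS_TUBERS
potato,Potato,GRAINS_ROOTS_TUBERS
bean,Bean,PULSES
almond,Almond,NUTS_SEEDS
milk,Milk (any species),DAIRY
beef_meat,Beef meat,MEAT_POULTRY_FISH
camel_meat,Camel meat,MEAT_POULTRY_FISH
goat_meat,Goat meat,MEAT_POULTRY_FISH
sheep_meat,Sheep meat,MEAT_POULTRY_FISH
poultry_meat,Poultry meat,MEAT_POULTRY_FISH
egg,Egg,EGGS
chard,Chard,DARK_GREEN_LEAFY
carrot,Carrot,VITA_FRUITS_VEG
parsley,Parsley,VITA_FRUITS_VEG
cucumber,Cucumber,OTHER_VEG
fennel,Fennel,OTHER_VEG
onion,Onion,OTHER_VEG
pea,Pea,OTHER_VEG
squash,Squash,OTHER_VEG
tomato,Tomato,OTHER_VEG
grape,Grape,OTHER_FRUITS
lemon,Lemon,OTHER_FRUITS
garlic,Garlic,UNCLASSIFIED
honey,Honey,UNCLASSIFIED
hot_pepper,Hot pepper,UNCLASSIFIED
olive_oil,Olive oil,UNCLASSIFIED
table_olive,Table olive,UNCLASSIFIED
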
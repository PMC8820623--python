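product_id,protein_g,vitamin_a_ug,vitamin_e_mg,thiamin_mg,riboflavin_mg,niacin_mg,pantothenic_acid_mg,folate_ug,vitamin_b12_ug,vitamin_c_mg,calcium_mg,copper_mg,iron_mg,magnesium_mg,potassium_mg,sodium_mg,zinc_mg,vitamin_b6_mg
oat,6.293,2.196,1.051,0.559,0.079,3.96,0.844,29.108,0.0,3.199,25.57,0.307,3.563,107.114,352.306,7.907,2.152,0.338
barley,12.104,1.68,0.642,0.283,0.114,3.023,0.857,36.253,0.0,5.243,27.654,0.421,2.081,134.579,423.106,6.685,1.409,0.294
wheat,6.601,1.555,0.818,0.276,0.145,3.291,0.783,29.869,0.0,6.107,56.397,0.339,3.121,99.746,461.398,6.606,2.459,0.315
potato,11.819,3.054,0.471,0.324,0.131,2.398,0.621,48.072,0.0,5.957,25.164,0.399,2.163,90.139,273.365,4.576,2.804,0.273
bean,17.094,2.804,0.315,0.561,0.163,2.512,0.462,341.42,0.0,3.065,71.563,0.901,5.487,153.304,1291.495,12.887,3.434,0.444
almond,13.308,0.921,22.876,0.194,0.926,3.581,0.415,42.685,0.0,0.0,153.991,1.248,2.229,313.504,683.081,0.711,1.887,0.141
milk,4.997,27.977,0.091,0.051,0.222,0.105,0.671,2.855,0.533,1.33,108.532,0.026,0.039,10.761,241.525,49.353,0.32,0.04
beef_meat,25.299,13.769,0.331,0.079,0.249,4.392,1.334,15.632,1.203,0.0,11.165,0.088,2.166,26.107,198.618,64.764,2.923,0.244
camel_meat,21.794,8.431,0.445,0.068,0.189,6.645,0.753,10.007,1.213,0.0,12.251,0.125,1.918,28.897,591.436,61.316,4.231,0.391
goat_meat,18.175,9.167,0.378,0.091,0.146,6.372,0.802,15.779,2.152,0.0,12.87,0.109,3.635,17.615,338.217,80.677,3.904,0.39
sheep_meat,28.072,10.854,0.579,0.062,0.182,5.341,1.002,5.682,2.906,0.0,10.152,0.125,2.036,25.948,223.425,80.453,3.825,0.288
poultry_meat,20.043,12.002,0.584,0.076,0.18,6.072,0.457,9.396,2.874,0.0,16.126,0.089,1.696,28.39,193.205,56.102,4.096,0.423
egg,9.889,161.029,1.285,0.05,0.472,0.065,1.244,41.041,0.915,0.0,68.772,0.085,1.626,9.016,158.977,145.986,0.897,0.206
chard,1.557,365.537,2.168,0.042,0.11,0.573,0.15,21.144,0.0,22.68,44.775,0.17,1.316,74.204,360.747,241.471,0.307,0.095
carrot,0.598,741.895,0.915,0.065,0.063,0.781,0.292,18.569,0.0,6.687,29.828,0.033,0.35,11.984,451.117,72.368,0.198,0.131
parsley,1.079,547.71,0.691,0.057,0.054,1.013,0.193,13.706,0.0,8.038,33.732,0.046,0.264,6.975,289.729,69.315,0.207,0.165
cucumber,1.243,25.55,0.43,0.049,0.041,0.899,0.244,22.653,0.0,11.057,23.476,0.049,0.438,9.342,220.232,3.66,0.368,0.093
fennel,0.845,18.109,0.531,0.067,0.054,0.652,0.295,14.207,0.0,18.453,20.092,0.048,0.433,8.988,305.537,6.575,0.353,0.067
onion,1.344,27.94,0.45,0.05,0.042,0.974,0.211,21.238,0.0,15.219,17.018,0.072,0.311,12.16,371.534,4.962,0.335,0.146
pea,0.875,32.345,0.507,0.068,0.046,0.721,0.195,39.083,0.0,8.064,16.495,0.043,0.26,12.29,281.268,4.267,0.226,0.08
squash,1.199,37.331,0.422,0.056,0.05,0.407,0.248,15.441,0.0,19.544,12.074,0.063,0.437,13.411,317.582,8.016,0.405,0.112
tomato,0.864,33.744,0.418,0.055,0.032,0.811,0.193,24.194,0.0,20.672,27.447,0.043,0.417,13.742,278.317,5.336,0.307,0.134
grape,0.671,4.051,0.266,0.058,0.039,0.182,0.074,5.273,0.0,28.158,11.379,0.077,0.29,9.54,247.028,1.642,0.127,0.078
lemon,0.491,3.434,0.133,0.059,0.032,0.142,0.076,5.742,0.0,19.874,14.435,0.086,0.353,10.766,139.198,1.135,0.098,0.092
garlic,1.996,7.73,5.735,0.072,0.049,0.6,0.31,9.681,0.0,7.198,33.511,0.104,0.862,19.764,169.231,293.309,0.632,0.158
honey,1.238,9.606,4.293,0.087,0.062,0.529,0.303,10.247,0.0,6.843,49.222,0.133,1.013,16.859,192.647,230.265,0.523,0.135
hot_pepper,1.818,19.739,4.359,0.135,0.061,0.45,0.329,8.488,0.0,8.881,37.621,0.13,1.026,22.512,138.416,241.535,0.769,0.184
olive_oil,2.817,9.375,2.692,0.15,0.054,0.72,0.33,7.224,0.0,5.505,31.783,0.09,0.905,15.33,179.128,228.715,0.346,0.155
table_olive,1.606,12.634,5.281,0.084,0.048,0.415,0.376,9.928,0.0,5.281,33.866,0.165,1.134,17.245,184.062,321.556,0.464,0.171
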
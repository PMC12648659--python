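solvent,absorbance,lambda_max
tetrahydrofuran,0.73,356
ethyl acetate,0.20,315
chloroform,0.53,371
acetone,0.21,344
"1,4-dioxane",0.07,320
diethyl ether,0.49,275
"1,2-dichloroethane",0.14,370
xylene,0.03,300
toluene,0.10,324
isopropanol,0.03,316
hexane,0.03,278
ethanol,0.48,369
acetonitrile,0.29,366
water,0.19,366
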
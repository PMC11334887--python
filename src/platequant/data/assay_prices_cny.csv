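name,category,market_price,package_qty,package_unit,per_test_qty,per_test_unit,share_denominator,printed_price_per_test
Bovine serum albumin standard,chemical,124,5,g,10,mg,91,0.003
Anhydrous ethanol,chemical,17,500,mL,1,mL,1,0.034
85% concentrated phosphoric acid,chemical,68,500,mL,2,mL,1,0.272
CBBG,chemical,232,10,g,2,mg,1,0.046
"Centrifugal tube, 10 mL",consumable,227,500,count,2,count,1,0.908
"Centrifugal tube, 50 mL",consumable,36,250,count,1,count,91,0.008
"Pipette tips, 5 mL",consumable,25,1000,count,2,count,1,0.050
"Pipette tips, 1 mL",consumable,82,1000,count,1,count,1,0.082
"Pipette tips, 200 uL",consumable,63,1000,count,1,count,1,0.063
96-well plate,consumable,10,1,count,1,count,91,0.110
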
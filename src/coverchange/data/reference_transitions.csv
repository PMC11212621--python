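from_code,to_code,label,cuba,protected,od,od_in_protected
1,1,Stable forest and shrubs,15.01,26.40,43.72,55.25
2,1,Mangrove to forest and shrubs,0.49,1.50,0.67,1.76
3,1,Soil without vegetation cover to forest and shrubs,0.36,0.08,0.30,0.06
4,1,Wetlands to forest and shrubs,0.53,0.86,0.43,0.42
5,1,Pine forest to forest and shrubs,0.94,2.02,3.18,6.06
6,1,Agriculture to forest and shrubs,20.69,5.91,21.75,8.57
7,1,Water bodies to forest and shrubs,0.11,0.25,0.03,0.04
2,2,Stable mangrove,3.67,12.23,1.27,2.46
1,2,Forest and shrubs to mangrove,0.21,0.85,0.22,0.63
3,2,Soil without vegetation cover to mangrove,0.19,0.71,0.11,0.28
4,2,Wetlands to mangrove,0.93,3.88,0.20,0.47
5,2,Pine forest to mangrove,0.00,0.00,0.00,0.00
6,2,Agriculture to mangrove,0.17,0.32,0.08,0.09
7,2,Water bodies to mangrove,0.61,1.84,0.26,0.48
3,3,Stable soil without vegetation cover,0.73,0.66,0.28,0.28
1,3,Forest and shrubs to soil without vegetation cover,0.01,0.02,0.01,0.02
2,3,Mangrove to soil without vegetation cover,0.00,0.01,0.00,0.00
4,3,Wetlands to soil without vegetation cover,0.06,0.21,0.03,0.06
5,3,Pine forest to soil without vegetation cover,0.00,0.00,0.00,0.00
6,3,Agriculture to soil without vegetation cover,0.36,0.07,0.11,0.04
7,3,Water bodies to soil without vegetation cover,0.00,0.02,0.00,0.01
4,4,Stable wetlands,2.36,6.12,0.65,0.95
1,4,Forest and shrubs to wetlands,0.13,0.37,0.08,0.15
2,4,Mangrove to wetlands,0.30,1.02,0.10,0.21
3,4,Soil without vegetation cover to wetlands,0.24,0.68,0.14,0.25
5,4,Pine forest to wetlands,0.00,0.00,0.00,0.00
6,4,Agriculture to wetlands,0.31,0.50,0.10,0.13
7,4,Water bodies to wetlands,0.35,1.16,0.18,0.36
5,5,Stable pine forest,0.74,1.80,2.50,5.23
1,5,Forest and shrubs to pine forest,0.31,0.54,0.82,1.39
2,5,Mangrove to pine forest,0.00,0.00,0.00,0.00
3,5,Soil without vegetation cover to pine forest,0.01,0.00,0.00,0.00
4,5,Wetlands to pine forest,0.00,0.00,0.00,0.00
6,5,Agriculture to pine forest,0.38,0.24,0.53,0.51
7,5,Water bodies to pine forest,0.03,0.00,0.01,0.00
6,6,Stable agriculture,37.50,6.04,15.23,6.22
1,6,Forest and shrubs to agriculture,1.30,0.88,2.60,1.86
2,6,Mangrove to agriculture,0.08,0.21,0.05,0.09
3,6,Soil without vegetation cover to agriculture,1.95,0.43,0.75,0.28
4,6,Wetlands to agriculture,0.18,0.23,0.08,0.10
5,6,Pine forest to agriculture,0.14,0.12,0.35,0.34
7,6,Water bodies to agriculture,0.11,0.25,0.05,0.07
7,7,Stable water bodies,8.00,20.83,2.82,4.56
1,7,Forest and shrubs to water bodies,0.04,0.01,0.03,0.00
2,7,Mangrove to water bodies,0.10,0.33,0.05,0.11
3,7,Soil without vegetation cover to water bodies,0.08,0.29,0.06,0.14
4,7,Wetlands to water bodies,0.03,0.10,0.01,0.03
5,7,Pine forest to water bodies,0.04,0.00,0.03,0.00
6,7,Agriculture to water bodies,0.21,0.02,0.12,0.00
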
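class_code,class_label,area,epoch,percentage
1,Forest and shrubs,cuba,1985,17.02
1,Forest and shrubs,cuba,2020,38.12
1,Forest and shrubs,protected,1985,29.08
1,Forest and shrubs,protected,2020,37.02
1,Forest and shrubs,od,1985,47.48
1,Forest and shrubs,od,2020,70.09
1,Forest and shrubs,od_in_protected,1985,59.31
1,Forest and shrubs,od_in_protected,2020,72.16
2,Mangrove,cuba,1985,4.64
2,Mangrove,cuba,2020,5.80
2,Mangrove,protected,1985,15.31
2,Mangrove,protected,2020,19.83
2,Mangrove,od,1985,2.15
2,Mangrove,od,2020,2.13
2,Mangrove,od_in_protected,1985,4.63
2,Mangrove,od_in_protected,2020,4.42
3,Soil without vegetation cover,cuba,1985,3.56
3,Soil without vegetation cover,cuba,2020,1.16
3,Soil without vegetation cover,protected,1985,2.85
3,Soil without vegetation cover,protected,2020,0.98
3,Soil without vegetation cover,od,1985,1.64
3,Soil without vegetation cover,od,2020,0.44
3,Soil without vegetation cover,od_in_protected,1985,1.31
3,Soil without vegetation cover,od_in_protected,2020,0.42
4,Wetland,cuba,1985,4.08
4,Wetland,cuba,2020,3.68
4,Wetland,protected,1985,11.39
4,Wetland,protected,2020,9.85
4,Wetland,od,1985,1.40
4,Wetland,od,2020,1.25
4,Wetland,od_in_protected,1985,2.03
4,Wetland,od_in_protected,2020,2.07
5,Pine forest,cuba,1985,1.86
5,Pine forest,cuba,2020,1.47
5,Pine forest,protected,1985,3.94
5,Pine forest,protected,2020,2.58
5,Pine forest,od,1985,6.06
5,Pine forest,od,2020,3.87
5,Pine forest,od_in_protected,1985,11.64
5,Pine forest,od_in_protected,2020,7.13
6,Agriculture,cuba,1985,59.62
6,Agriculture,cuba,2020,41.26
6,Agriculture,protected,1985,13.09
6,Agriculture,protected,2020,8.16
6,Agriculture,od,1985,37.92
6,Agriculture,od,2020,19.11
6,Agriculture,od_in_protected,1985,15.57
6,Agriculture,od_in_protected,2020,8.95
7,Water bodies,cuba,1985,9.23
7,Water bodies,cuba,2020,8.50
7,Water bodies,protected,1985,24.34
7,Water bodies,protected,2020,21.58
7,Water bodies,od,1985,3.35
7,Water bodies,od,2020,3.11
7,Water bodies,od_in_protected,1985,5.53
7,Water bodies,od_in_protected,2020,4.85
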
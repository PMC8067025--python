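no,classification,factor
1,Anthropogenic factors,Distance to factory (m)
2,Anthropogenic factors,Distance to road (m)
3,Anthropogenic factors,Road density (m2/1.46 km2)
,Anthropogenic factors,Human population density (n/1.46 km2)
4,Anthropogenic factors,Distance to rice paddy (m)
5,Anthropogenic factors,Distance to field (m)
6,Anthropogenic factors,Field density (m2/1.46 km2)
7,Anthropogenic factors,Distance to trail (m)
8,Forest,Distance to deciduous forest (m)
9,Forest,Density of deciduous forest (m2/1.46 km2)
10,Forest,Density of coniferous forest (m2/1.46 km2)
11,Forest,Density of forest (m2/1.46 km2)
12,Forest,Age class (1 (young) to 9 (old))
13,Forest,Diameter class (0 (young) to 3 (large))
14,Forest,Crown density (1 (sparse) to 3 (dense))
15,Landscape,Distance to stream (m)
16,Landscape,Stream density (m2/1.46 km2)
17,Landscape,Lake density (m2/1.46 km2)
18,Landscape,Altitude (m)
19,Landscape,Aspect (1 to 360)
20,Landscape,Slope (deg)
21,Soil map,Soil drainage (1 (bad) to 4 (very good))
22,Soil map,Degree of rock exposure (1 (little) to 4 (a lot))
23,Soil map,Soil type (1 (no) to 3 (many))
24,Soil map,Degree of wind exposure (1 (exposed) to 3 (closed))
25,Soil map,Distance to wet soil (m)
26,Soil map,Wet soil density (m2/1.46 km2)
27,Soil map,Slant type (1 (rising slope) to 3 (falling slope))
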
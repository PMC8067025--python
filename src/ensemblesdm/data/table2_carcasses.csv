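id,observed_date,collected_date,sex,age_class,estimated_age,pregnant
1,2010.03.16,2010.03.19,M,Juvenile,>1,
2,2010.03.23,2010.04.01,F,Adult,>15,Y
3,2010.03.25,2010.03.26,M,Yearling,<1,
4,2010.03.28,2010.04.01,,Adult,5-6,
5,2010.03.31,2010.04.02,,Juvenile,>1,
6,2010.04.07,2010.04.07,F,Adult,>10,Y
7,2010.04.03,2010.04.08,F,Adult,>10,Y
8,2010.04.09,2010.04.09,M,Juvenile,>1,
9,2010.04.09,2010.04.09,,Yearling,<1,
10,2010.04.10,2010.04.10,,Juvenile,<1,
11,2010.04.10,2010.04.10,M,Juvenile,>1,
12,2010.04.11,2010.04.11,F,Adult,5-8,Y
13,2010.04.10,2010.04.10,M,Juvenile,<1,
14,2010.04.11,2010.04.11,F,Juvenile,>1,
15,2010.04.11,2010.04.11,,Juvenile,<1,
16,2010.04.20,2010.04.21,F,Adult,,
17,2010.04.20,2010.04.21,,Juvenile,,
18,2010.04.21,2010.04.29,,,,
19,2010.04.21,2010.04.21,,Juvenile,,
20,2010.04.21,2010.04.21,,Juvenile,,
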
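id,name
1,Segmentation
2,Taking out
3,Local quality
4,Asymmetry
5,Merging
6,Universality
7,Nested doll
8,Anti-weight
9,Preliminary anti-action
10,Preliminary action
11,Beforehand cushioning
12,Equipotentiality
13,The other way round
14,Spheroidality
15,Dynamics
16,Partial or excessive actions
17,Another dimension
18,Mechanical vibration
19,Periodic action
20,Continuity of useful action
21,Skipping
22,Blessing in disguise
23,Feedback
24,Intermediary
25,Self-service
26,Copying
27,Cheap short-living objects
28,Mechanics substitution
29,Pneumatics and hydraulics
30,Flexible shells and thin films
31,Porous materials
32,Color changes
33,Homogeneity
34,Discarding and recovering
35,Parameter changes
36,Phase transitions
37,Thermal expansion
38,Strong oxidants
39,Inert atmosphere
40,Composite materials
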
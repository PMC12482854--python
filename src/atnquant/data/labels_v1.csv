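id,name,tissue
1,3rd Ventricle,CSF
2,4th Ventricle,CSF
3,Left Lateral Ventricle,CSF
4,Right Lateral Ventricle,CSF
5,Left Inferior Lateral Ventricle,CSF
6,Right Inferior Lateral Ventricle,CSF
7,Left Cerebral White Matter,WM
8,Right Cerebral White Matter,WM
9,Left Cerebellum White Matter,WM
10,Right Cerebellum White Matter,WM
11,Left Accumbens Area,GM
12,Right Accumbens Area,GM
13,Left Amygdala,GM
14,Right Amygdala,GM
15,Left Caudate,GM
16,Right Caudate,GM
17,Left Cerebellum Exterior,GM
18,Right Cerebellum Exterior,GM
19,Left Hippocampus,GM
20,Right Hippocampus,GM
21,Left Pallidum,GM
22,Right Pallidum,GM
23,Left Putamen,GM
24,Right Putamen,GM
25,Left Thalamus Proper,GM
26,Right Thalamus Proper,GM
27,Left Ventral DC,GM
28,Right Ventral DC,GM
29,Left Basal Forebrain,GM
30,Right Basal Forebrain,GM
31,Brain Stem,GM
32,Optic Chiasm,GM
33,Cerebellar Vermal Lobules I-V,GM
34,Cerebellar Vermal Lobules VI-X,GM
35,Left Anterior Cingulate Gyrus,GM
36,Right Anterior Cingulate Gyrus,GM
37,Left Anterior Insula,GM
38,Right Anterior Insula,GM
39,Left Anterior Orbital Gyrus,GM
40,Right Anterior Orbital Gyrus,GM
41,Left Angular Gyrus,GM
42,Right Angular Gyrus,GM
43,Left Calcarine Cortex,GM
44,Right Calcarine Cortex,GM
45,Left Central Operculum,GM
46,Right Central Operculum,GM
47,Left Cuneus,GM
48,Right Cuneus,GM
49,Left Entorhinal Area,GM
50,Right Entorhinal Area,GM
51,Left Frontal Operculum,GM
52,Right Frontal Operculum,GM
53,Left Frontal Pole,GM
54,Right Frontal Pole,GM
55,Left Fusiform Gyrus,GM
56,Right Fusiform Gyrus,GM
57,Left Gyrus Rectus,GM
58,Right Gyrus Rectus,GM
59,Left Inferior Occipital Gyrus,GM
60,Right Inferior Occipital Gyrus,GM
61,Left Inferior Temporal Gyrus,GM
62,Right Inferior Temporal Gyrus,GM
63,Left Lingual Gyrus,GM
64,Right Lingual Gyrus,GM
65,Left Lateral Orbital Gyrus,GM
66,Right Lateral Orbital Gyrus,GM
67,Left Middle Cingulate Gyrus,GM
68,Right Middle Cingulate Gyrus,GM
69,Left Medial Frontal Cortex,GM
70,Right Medial Frontal Cortex,GM
71,Left Middle Frontal Gyrus,GM
72,Right Middle Frontal Gyrus,GM
73,Left Middle Occipital Gyrus,GM
74,Right Middle Occipital Gyrus,GM
75,Left Medial Orbital Gyrus,GM
76,Right Medial Orbital Gyrus,GM
77,Left Postcentral Gyrus Medial Segment,GM
78,Right Postcentral Gyrus Medial Segment,GM
79,Left Precentral Gyrus Medial Segment,GM
80,Right Precentral Gyrus Medial Segment,GM
81,Left Superior Frontal Gyrus Medial Segment,GM
82,Right Superior Frontal Gyrus Medial Segment,GM
83,Left Middle Temporal Gyrus,GM
84,Right Middle Temporal Gyrus,GM
85,Left Occipital Pole,GM
86,Right Occipital Pole,GM
87,Left Occipital Fusiform Gyrus,GM
88,Right Occipital Fusiform Gyrus,GM
89,Left Opercular Part of the Inferior Frontal Gyrus,GM
90,Right Opercular Part of the Inferior Frontal Gyrus,GM
91,Left Orbital Part of the Inferior Frontal Gyrus,GM
92,Right Orbital Part of the Inferior Frontal Gyrus,GM
93,Left Posterior Cingulate Gyrus,GM
94,Right Posterior Cingulate Gyrus,GM
95,Left Precuneus,GM
96,Right Precuneus,GM
97,Left Parahippocampal Gyrus,GM
98,Right Parahippocampal Gyrus,GM
99,Left Posterior Insula,GM
100,Right Posterior Insula,GM
101,Left Parietal Operculum,GM
102,Right Parietal Operculum,GM
103,Left Postcentral Gyrus,GM
104,Right Postcentral Gyrus,GM
105,Left Posterior Orbital Gyrus,GM
106,Right Posterior Orbital Gyrus,GM
107,Left Planum Polare,GM
108,Right Planum Polare,GM
109,Left Precentral Gyrus,GM
110,Right Precentral Gyrus,GM
111,Left Planum Temporale,GM
112,Right Planum Temporale,GM
113,Left Subcallosal Area,GM
114,Right Subcallosal Area,GM
115,Left Superior Frontal Gyrus,GM
116,Right Superior Frontal Gyrus,GM
117,Left Supplementary Motor Cortex,GM
118,Right Supplementary Motor Cortex,GM
119,Left Supramarginal Gyrus,GM
120,Right Supramarginal Gyrus,GM
121,Left Superior Occipital Gyrus,GM
122,Right Superior Occipital Gyrus,GM
123,Left Superior Parietal Lobule,GM
124,Right Superior Parietal Lobule,GM
125,Left Superior Temporal Gyrus,GM
126,Right Superior Temporal Gyrus,GM
127,Left Temporal Pole,GM
128,Right Temporal Pole,GM
129,Left Triangular Part of the Inferior Frontal Gyrus,GM
130,Right Triangular Part of the Inferior Frontal Gyrus,GM
131,Left Transverse Temporal Gyrus,GM
132,Right Transverse Temporal Gyrus,GM
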
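# Molecular descriptors of the virtual-screening hits: hydrogen-bond donors
# and acceptors, molecular mass (g/mol) and logP, with the published
# drug-likeness marking (`reported_pass`).  One duplicate descriptor row for
# ZINC04773602 (mass misprinted 358.329) was dropped.
ligand,donors,acceptors,mass,logp,reported_pass
ZINC29590259,4,13,696.129,5.73,false
ZINC29590263,4,13,696.129,5.73,false
ZINC18141294,1,9,453.482,4.43,false
ZINC01690699,4,8,548.606,6.89,false
ZINC04773602,2,2,358.529,6.03,false
ZINC29590257,4,13,696.129,5.73,false
ZINC13099051,1,3,447.644,5.66,false
ZINC01639634,4,9,488.507,5.61,false
ZINC18057104,3,9,506.566,5.00,false
ZINC04783229,2,6,476.580,6.47,false
ZINC01694053,6,8,488.979,2.06,true
ZINC01572309,4,8,474.571,5.84,false
ZINC01707130,3,8,299.290,-0.28,true
ZINC01568793,0,6,484.596,4.28,true
ZINC13152284,2,4,392.458,6.51,false
ZINC00084617,1,6,333.323,2.71,true
ZINC13208966,2,2,275.351,3.91,true
ZINC04720972,3,5,382.419,6.01,false
ZINC11677172,2,6,496.575,3.78,true
ZINC00393674,2,5,314.348,3.11,true
ZINC01701460,0,2,367.279,7.26,false
ZINC15952559,3,5,271.251,3.07,true
ZINC11677178,2,6,496.575,3.78,true
ZINC12671898,0,4,412.570,4.70,true
ZINC17353914,2,5,472.629,4.96,true
ZINC01573829,0,3,353.450,5.98,false
ZINC01577889,2,4,392.458,5.41,false
ZINC29590275,1,3,447.003,6.38,false
ZINC01726776,0,5,398.853,5.98,false
ZINC17465979,6,10,546.528,5.26,false
ZINC05462670,6,10,546.528,5.26,false
ZINC05462674,6,10,546.528,5.26,false
ZINC12672242,2,3,410.524,5.61,false
ZINC17465983,6,10,546.528,5.26,false
ZINC01668429,6,11,499.531,1.34,false
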
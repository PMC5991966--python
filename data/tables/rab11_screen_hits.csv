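# Consensus top-scoring virtual-screening hits against the Rab11 representative
# structures: docking free energy (AutoDock Vina) and the number of profiled
# protein-ligand interactions at the assigned site.  `best` marks, per ligand,
# the target structure in which it scored best.
ligand,target,site,energy_kcal_mol,n_interactions,best
ZINC29590259,4LX0_C,site1,-8.9,7,true
ZINC29590259,5C46_F,site1,-8.2,10,false
ZINC29590259,1OIV_A,site1,-8.5,5,false
ZINC29590259,4OJK_A,site2,-8.4,4,false
ZINC29590263,4LX0_C,site1,-9.0,6,true
ZINC29590263,4OJK_A,site2,-8.3,4,false
ZINC18141294,1OIV_A,site1,-8.9,5,true
ZINC18141294,4OJK_A,site2,-8.0,4,false
ZINC01690699,4LX0_C,site1,-9.9,2,true
ZINC01690699,1OIV_A,site1,-8.6,6,false
ZINC01690699,4C4P_A,site2,-8.6,5,false
ZINC01690699,5C46_F,site1,-8.7,3,false
ZINC01690699,4UJ5_B,site2,-8.9,2,false
ZINC01690699,1YZK_A,site2,-8.6,3,false
ZINC01690699,5JCZ_D,site1,-8.3,4,false
ZINC04773602,1YZK_A,site2,-8.0,10,true
ZINC29590257,5C46_F,site1,-8.2,9,true
ZINC29590257,4LX0_C,site1,-8.7,4,false
ZINC29590257,4OJK_A,site2,-8.4,4,false
ZINC13099051,4LX0_C,site1,-9.4,5,true
ZINC13099051,1OIV_A,site1,-8.6,3,false
ZINC01639634,4LX0_C,site1,-8.6,5,true
ZINC18057104,1OIV_A,site1,-9.1,6,true
ZINC18057104,4LX0_C,site1,-8.8,4,false
ZINC18057104,4UJ5_B,site2,-8.3,2,false
ZINC04783229,4LX0_C,site1,-9.6,3,true
ZINC04783229,4OJK_A,site2,-9.0,1,false
ZINC04783229,4UJ5_B,site1,-8.5,2,false
ZINC04783229,4C4P_A,site2,-8.4,2,false
ZINC01694053,4LX0_C,site1,-8.6,6,true
ZINC01694053,4C4P_A,site2,-8.3,4,false
ZINC01572309,1YZK_A,site2,-8.8,4,true
ZINC01572309,4C4P_A,site2,-8.3,5,false
ZINC01572309,4OJK_A,site2,-8.4,5,false
ZINC01572309,1OIV_A,site1,-8.6,3,false
ZINC01707130,4LX0_C,site1,-8.5,4,true
ZINC01568793,4LX0_C,site1,-9.0,5,true
ZINC01568793,5JCZ_D,site1,-8.6,4,false
ZINC01568793,1OIV_A,site1,-8.5,6,false
ZINC01568793,4C4P_A,site2,-8.3,3,false
ZINC01568793,4UJ5_B,site2,-8.0,3,false
ZINC13152284,4LX0_C,site1,-9.2,3,true
ZINC13152284,1OIV_A,site1,-9.1,1,false
ZINC13152284,4UJ5_B,site2,-8.3,1,false
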
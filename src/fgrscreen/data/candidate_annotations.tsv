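protein_id	region	cell_class	level
Cd200	cerebral_cortex	neuronal	high
Cd200	cerebral_cortex	glial	high
Cd200	hippocampus	neuronal	medium
Cd200	caudate	neuronal	low
Cd200	cerebellum	molecular_layer	low
Cd200	cerebellum	granular_layer	high
A2m	cerebral_cortex	neuronal	high
A2m	cerebral_cortex	endothelial	high
A2m	hippocampus	neuronal	medium
A2m	caudate	neuronal	medium
A2m	cerebellum	molecular_layer	low
Ubb	cerebral_cortex	neuronal	medium
Ubb	cerebral_cortex	glial	medium
Ubb	cerebral_cortex	neuropil	low
Ubb	hippocampus	neuronal	medium
Ubb	caudate	neuronal	low
Ubb	cerebellum	purkinje	medium
Serpini1	cerebral_cortex	neuropil	medium
Serpini1	cerebral_cortex	neuronal	low
Serpini1	cerebral_cortex	glial	medium
Serpini1	hippocampus	neuronal	medium
Serpini1	caudate	neuronal	medium
Serpini1	cerebellum	purkinje	low
Serpini1	cerebellum	granular_layer	low
Otub1	cerebral_cortex	neuropil	low
Otub1	cerebral_cortex	endothelial	medium
Otub1	hippocampus	neuronal	low
Otub1	hippocampus	glial	low
Otub1	caudate	other	not_detected
Otub1	cerebellum	purkinje	medium
Otub1	cerebellum	granular_layer	medium
Ube1	cerebral_cortex	endothelial	low
Ube1	cerebral_cortex	neuropil	low
Ube1	hippocampus	glial	low
Ube1	hippocampus	neuronal	low
Ube1	caudate	glial	low
Ube1	caudate	neuronal	low
Ube1	cerebellum	purkinje	high
Ube1	cerebellum	molecular_layer	high
Sned1	cerebral_cortex	endothelial	low
Sned1	hippocampus	glial	low
Sned1	caudate	other	not_detected
Sned1	cerebellum	purkinje	low
Cd93	cerebral_cortex	endothelial	low
Cd93	hippocampus	other	not_detected
Cd93	caudate	other	not_detected
Cd93	cerebellum	other	not_detected
Fabp3	cerebral_cortex	other	not_detected
Fabp3	hippocampus	neuronal	low
Fabp3	caudate	other	not_detected
Fabp3	cerebellum	other	not_detected
Serpina3	cerebral_cortex	other	not_detected
Serpina3	hippocampus	other	not_detected
Serpina3	caudate	other	not_detected
Serpina3	cerebellum	molecular_layer	low
Eno3	cerebral_cortex	other	not_detected
Eno3	hippocampus	other	not_detected
Eno3	caudate	other	not_detected
Eno3	cerebellum	other	not_detected
Fetub	cerebral_cortex	other	not_detected
Fetub	hippocampus	other	not_detected
Fetub	caudate	other	not_detected
Fetub	cerebellum	other	not_detected
Hrg	cerebral_cortex	other	not_detected
Hrg	hippocampus	other	not_detected
Hrg	caudate	other	not_detected
Hrg	cerebellum	other	not_detected
C4	cerebral_cortex	other	not_detected
C4	hippocampus	other	not_detected
C4	caudate	other	not_detected
C4	cerebellum	other	not_detected
Ces1	cerebral_cortex	neuronal	low
Ces1	hippocampus	neuronal	low
Ces1	caudate	other	not_detected
Ces1	cerebellum	granular_layer	low
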
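original,L3,L2,L1,CL_Label,CL_ID,match_level
Endothelial Cell,endothelial cell,endothelial cell,endothelial,endothelial cell,CL:0000115,exactMatch
Endothelial Cell of Sinusoid,endothelial cell of sinusoid,endothelial cell,endothelial,endothelial cell of sinusoid,CL:0002262,exactMatch
T Cell,t cell,t cell,immune,T cell,CL:0000084,exactMatch
CD8+ T Cell,cd8+ t cell,t cell,immune,"CD8-positive, alpha-beta T cell",CL:0000625,exactMatch
B Cell,b cell,b cell,immune,B cell,CL:0000236,exactMatch
Macrophage,macrophage,macrophage,immune,macrophage,CL:0000235,exactMatch
Inflammatory Macrophage,inflammatory macrophage,macrophage,immune,inflammatory macrophage,CL:0000863,exactMatch
Fibroblast,fibroblast,fibroblast,mesenchymal,fibroblast,CL:0000057,exactMatch
Epithelial Cell,epithelial cell,epithelial cell,epithelial,epithelial cell,CL:0000066,exactMatch
Neuron,neuron,neuron,neural,neuron,CL:0000540,narrowMatch
Hematopoietic Stem Cell,hematopoietic stem cell,hematopoietic precursor cell,hematopoietic precursor,hematopoietic stem cell,CL:0000037,exactMatch
Unknown,unknown,unknown,unknown,cell,CL:0000000,narrowMatch
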
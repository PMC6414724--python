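species_id,acronym,origin,specialization,preference,phenology
Columba palumbus,CPAL,Mediterranean,generalist,forest,sedentary
Streptopelia turtur,STUR,Mediterranean,specialist,forest,migrant
Cuculus canorus,CCAN,Eurosiberian,generalist,forest,migrant
Picus viridis,PVIR,Eurosiberian,generalist,forest,sedentary
Alauda arvensis,AARV,Eurosiberian,specialist,open,sedentary
Troglodytes troglodytes,TTRO,Eurosiberian,generalist,forest,sedentary
Prunella modularis,PMOD,Eurosiberian,generalist,open,sedentary
Erithacus rubecula,ERUB,Eurosiberian,generalist,forest,sedentary
Saxicola torquata,STOR,Eurosiberian,specialist,open,sedentary
Turdus merula,TMER,Eurosiberian,generalist,forest,sedentary
Sylvia undata,SUND,Mediterranean,specialist,open,sedentary
Sylvia communis,SCOM,Mediterranean,specialist,open,migrant
Sylvia atricapilla,SATR,Eurosiberian,specialist,forest,migrant
Phylloscopus ibericus,PIBE,Eurosiberian,specialist,forest,migrant
Regulus ignicapilla,RIGN,Eurosiberian,specialist,forest,sedentary
Lophophanes cristatus,PCRI,Eurosiberian,specialist,forest,sedentary
Periparus ater,PATE,Eurosiberian,specialist,forest,sedentary
Parus major,PMAJ,Eurosiberian,specialist,forest,sedentary
Certhia brachydactyla,CBRA,Eurosiberian,specialist,forest,sedentary
Oriolus oriolus,OORI,Eurosiberian,specialist,forest,migrant
Lanius collurio,LCOL,Eurosiberian,specialist,open,migrant
Garrulus glandarius,GGLA,Eurosiberian,specialist,forest,sedentary
Fringilla coelebs,FCOE,Eurosiberian,generalist,forest,sedentary
Serinus serinus,SSER,Mediterranean,generalist,forest,migrant
Carduelis chloris,CCHL,Mediterranean,specialist,forest,migrant
Carduelis cannabina,CCANN,Mediterranean,specialist,open,sedentary
Emberiza cia,ECIA,Eurosiberian,specialist,open,sedentary
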
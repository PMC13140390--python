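eggNOG	description	tnseq_group	partition_species	partition_genus	partition_family	partition_phylum
COG0008	Glutamate--tRNA ligase	Intermediate	Persistent	Persistent	Persistent	Persistent
COG0008	Glutamine--tRNA ligase	Intermediate	Persistent	Persistent	Persistent	Persistent
COG0013	Alanine--tRNA ligase	Intermediate	Persistent	Shell	Shell	Shell
COG0016	Phenylalanine--tRNA ligase alpha subunit	Highly permissive	Persistent	Persistent	Persistent	Persistent
COG0017	Aspartate--tRNA(Asp/Asn) ligase	Intermediate	Persistent	Persistent	Persistent	Persistent
COG0017	Asparagine--tRNA ligase	Less permissive	Persistent	Persistent	Persistent	Persistent
COG0018	Arginine--tRNA ligase	Intermediate	Persistent	Persistent	Persistent	Persistent
COG0024	Methionine aminopeptidase	Less permissive	Persistent	Persistent	Persistent	Shell
COG0048	30S ribosomal protein S12	Less permissive	Persistent	Persistent	Persistent	Persistent
COG0049	30S ribosomal protein S7	Less permissive	Persistent	Persistent	Persistent	Persistent
COG0051	30S ribosomal protein S10	Less permissive	Persistent	Persistent	Persistent	Persistent
COG0052	30S ribosomal protein S2	Intermediate	Persistent	Persistent	Persistent	Persistent
COG0060	Isoleucine--tRNA ligase	Intermediate	Persistent	Persistent	Persistent	Persistent
COG0081	50S ribosomal protein L1	Intermediate	Persistent	Persistent	Persistent	Persistent
COG0087	50S ribosomal protein L3	Intermediate	Persistent	Persistent	Persistent	Persistent
COG0088	50S ribosomal protein L4	Less permissive	Persistent	Persistent	Persistent	Persistent
COG0089	50S ribosomal protein L23	Intermediate	Persistent	Persistent	Persistent	Persistent
COG0090	50S ribosomal protein L2	Less permissive	Persistent	Persistent	Persistent	Persistent
COG0091	50S ribosomal protein L22	Less permissive	Persistent	Persistent	Persistent	Persistent
COG0094	50S ribosomal protein L5	Less permissive	Persistent	Persistent	Persistent	Persistent
COG0096	30S ribosomal protein S8	Less permissive	Persistent	Persistent	Persistent	Persistent
COG0097	50S ribosomal protein L6	Intermediate	Persistent	Persistent	Persistent	Persistent
COG0098	30S ribosomal protein S5	Less permissive	Persistent	Persistent	Persistent	Persistent
COG0099	30S ribosomal protein S13	Less permissive	Persistent	Persistent	Persistent	Persistent
COG0100	30S ribosomal protein S11	Less permissive	Persistent	Persistent	Persistent	Persistent
COG0102	50S ribosomal protein L13	Intermediate	Persistent	Persistent	Persistent	Persistent
COG0103	30S ribosomal protein S9	Less permissive	Persistent	Persistent	Persistent	Persistent
COG0124	Histidine--tRNA ligase	Less permissive	Persistent	Shell	Persistent	Persistent
COG0162	Tyrosine--tRNA ligase	Highly permissive	Persistent	Persistent	Persistent	Persistent
COG0172	Serine--tRNA ligase	Less permissive	Persistent	Persistent	Persistent	Persistent
COG0180	Tryptophan--tRNA ligase	Intermediate	Persistent	Persistent	Persistent	Persistent
COG0186	30S ribosomal protein S17	Less permissive	Persistent	Persistent	Persistent	Persistent
COG0195	Transcription termination/antitermination protein NusA	Intermediate	Persistent	Persistent	Persistent	Persistent
COG0197	50S ribosomal protein L16	Less permissive	Persistent	Persistent	Persistent	Persistent
COG0198	50S ribosomal protein L24	Intermediate	Persistent	Persistent	Persistent	Persistent
COG0199	30S ribosomal protein S14 type Z	Less permissive	Persistent	Persistent	Persistent	Persistent
COG0201	Protein translocase subunit SecY	Intermediate	Persistent	Persistent	Persistent	Persistent
COG0202	DNA-directed RNA polymerase subunit alpha	Intermediate	Persistent	Persistent	Persistent	Persistent
COG0256	50S ribosomal protein L18	Intermediate	Persistent	Persistent	Persistent	Persistent
COG0361	Translation initiation factor IF-1	Intermediate	Persistent	Persistent	Persistent	Persistent
COG0442	Proline--tRNA ligase	Highly permissive	Persistent	Persistent	Persistent	Persistent
COG0462	Ribose-phosphate pyrophosphokinase	Highly permissive	Persistent	Persistent	Persistent	Persistent
COG0462	Ribose-phosphate pyrophosphokinase	Intermediate	Persistent	Persistent	Persistent	Persistent
COG0470	DNA polymerase III subunit delta'	Intermediate	Persistent	Persistent	Persistent	Shell
COG0470	Belongs to the ribF family	Intermediate	Persistent	Shell	Shell	Shell
COG0480	Elongation factor G	Highly permissive	Persistent	Persistent	Persistent	Persistent
COG0480	Elongation factor G	Intermediate	Persistent	Persistent	Persistent	Persistent
COG0495	Leucine--tRNA ligase	Highly permissive	Persistent	Persistent	Persistent	Persistent
COG0504	CTP synthase	Intermediate	Persistent	Persistent	Persistent	Persistent
COG0522	30S ribosomal protein S4	Less permissive	Persistent	Persistent	Persistent	Persistent
COG0525	Valine--tRNA ligase	Intermediate	Persistent	Persistent	Persistent	Persistent
COG0532	Translation initiation factor IF-2	Intermediate	Persistent	Persistent	Persistent	Persistent
COG0592	Beta sliding clamp	Intermediate	Persistent	Persistent	Persistent	Persistent
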
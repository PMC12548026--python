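organism	superkingdom	phylum	species
Escherichia coli	Bacteria	Pseudomonadota	Escherichia coli
Escherichia coli K-12	Bacteria	Pseudomonadota	Escherichia coli
Escherichia coli str. K-12 substr. MG1655	Bacteria	Pseudomonadota	Escherichia coli
Pseudomonas aeruginosa	Bacteria	Pseudomonadota	Pseudomonas aeruginosa
Pseudomonas aeruginosa PAO1	Bacteria	Pseudomonadota	Pseudomonas aeruginosa
Salmonella enterica	Bacteria	Pseudomonadota	Salmonella enterica
Vibrio cholerae	Bacteria	Pseudomonadota	Vibrio cholerae
Bacillus subtilis	Bacteria	Bacillota	Bacillus subtilis
Bacillus subtilis subsp. subtilis str. 168	Bacteria	Bacillota	Bacillus subtilis
Staphylococcus aureus	Bacteria	Bacillota	Staphylococcus aureus
Listeria monocytogenes	Bacteria	Bacillota	Listeria monocytogenes
Mycobacterium tuberculosis	Bacteria	Actinomycetota	Mycobacterium tuberculosis
Streptomyces coelicolor	Bacteria	Actinomycetota	Streptomyces coelicolor
Synechocystis sp. PCC 6803	Bacteria	Cyanobacteriota	Synechocystis sp. PCC 6803
Helicobacter pylori	Bacteria	Campylobacterota	Helicobacter pylori
Haloferax volcanii	Archaea	Euryarchaeota	Haloferax volcanii
Sulfolobus acidocaldarius	Archaea	Thermoproteota	Sulfolobus acidocaldarius
Saccharomyces cerevisiae	Eukaryota	Ascomycota	Saccharomyces cerevisiae
Homo sapiens	Eukaryota	Chordata	Homo sapiens
Escherichia virus T4	Viruses	Uroviricota	Escherichia virus T4
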
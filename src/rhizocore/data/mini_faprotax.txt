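# Mini taxonomy-to-function rule set (FAPROTAX flat-file dialect).
# Functions and taxa relevant to wheat rhizosphere soil communities;
# header line = function name <TAB> metadata, indented lines = taxon
# patterns, add_group: includes another function's clauses.

nitrification	elements:N,O	nitrite/ammonia oxidisers
	*Nitrospira*
	*Nitrosomonas*
	*Nitrobacter*

nitrogen_fixation	elements:N	diazotrophs incl. rhizobial symbionts
	*Bradyrhizobium*
	*Rhizobium*
	*Mesorhizobium*
	*Azospirillum*

denitrification	elements:N	nitrate/nitrite reducers to gaseous N
	*Bradyrhizobium*
	*Rhodoplanes*
	*Paracoccus*

aromatic_compound_degradation	elements:C	degraders of aromatic carbon
	*Bradyrhizobium*
	*Sphingomonas*
	*Burkholderia*

ureolysis	elements:N	urea hydrolysers
	*Pseudarthrobacter*
	*Sporosarcina*

chitinolysis	elements:C,N	chitin degraders
	*Streptosporangium*
	*Chitinophaga*

cellulolysis	elements:C	cellulose degraders
	*Cellulomonas*
	*Streptosporangium*

methylotrophy	elements:C	C1-compound utilisers
	*Methylobacterium*
	*Hyphomicrobium*

methanol_oxidation	elements:C	subset of methylotrophy
	add_group:methylotrophy

fermentation	elements:C	fermentative chemoheterotrophs
	*Clostridium*
	*Lactobacillus*
	*Cellulomonas*

aerobic_chemoheterotrophy	elements:C	aerobic organic-carbon oxidisers
	*Sphingomonas*
	*Pseudarthrobacter*
	*Devosia*
	*Burkholderia*
	*Baekduia*
	*Solirubrobacter*

chemoheterotrophy	elements:C	all chemoheterotrophs
	add_group:aerobic_chemoheterotrophy
	add_group:fermentation
	*Bradyrhizobium*
	*Rhodoplanes*
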
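treatment	pathway	state
control	Pi_translocator	NOT_DOWNREGULATED
control	GBSS	NOT_DOWNREGULATED
control	PGM	NOT_DOWNREGULATED
control	glucosyltransferase	NOT_DOWNREGULATED
control	ACCase	PARTIAL
control	GAR_synthase_transformylase	PARTIAL
control	nitrate_reductase	PARTIAL
control	NADH_GOGAT	PARTIAL
control	fatty_acid_desaturase	NOT_DOWNREGULATED
control	arachin_biosynthesis	NOT_DOWNREGULATED
N	Pi_translocator	NOT_DOWNREGULATED
N	GBSS	NOT_DOWNREGULATED
N	PGM	NOT_DOWNREGULATED
N	glucosyltransferase	NOT_DOWNREGULATED
N	ACCase	PARTIAL
N	GAR_synthase_transformylase	PARTIAL
N	nitrate_reductase	FULL
N	NADH_GOGAT	FULL
N	fatty_acid_desaturase	NOT_DOWNREGULATED
N	arachin_biosynthesis	PARTIAL
Pi	Pi_translocator	NOT_DOWNREGULATED
Pi	GBSS	NOT_DOWNREGULATED
Pi	PGM	NOT_DOWNREGULATED
Pi	glucosyltransferase	PARTIAL
Pi	ACCase	PARTIAL
Pi	GAR_synthase_transformylase	PARTIAL
Pi	nitrate_reductase	FULL
Pi	NADH_GOGAT	FULL
Pi	fatty_acid_desaturase	NOT_DOWNREGULATED
Pi	arachin_biosynthesis	NOT_DOWNREGULATED
S	Pi_translocator	NOT_DOWNREGULATED
S	GBSS	NOT_DOWNREGULATED
S	PGM	NOT_DOWNREGULATED
S	glucosyltransferase	NOT_DOWNREGULATED
S	ACCase	PARTIAL
S	GAR_synthase_transformylase	NOT_DOWNREGULATED
S	nitrate_reductase	FULL
S	NADH_GOGAT	FULL
S	fatty_acid_desaturase	PARTIAL
S	arachin_biosynthesis	PARTIAL
K	Pi_translocator	NOT_DOWNREGULATED
K	GBSS	NOT_DOWNREGULATED
K	PGM	NOT_DOWNREGULATED
K	glucosyltransferase	NOT_DOWNREGULATED
K	ACCase	PARTIAL
K	GAR_synthase_transformylase	PARTIAL
K	nitrate_reductase	PARTIAL
K	NADH_GOGAT	FULL
K	fatty_acid_desaturase	PARTIAL
K	arachin_biosynthesis	NOT_DOWNREGULATED
NPKS	Pi_translocator	NOT_DOWNREGULATED
NPKS	GBSS	NOT_DOWNREGULATED
NPKS	PGM	NOT_DOWNREGULATED
NPKS	glucosyltransferase	NOT_DOWNREGULATED
NPKS	ACCase	PARTIAL
NPKS	GAR_synthase_transformylase	PARTIAL
NPKS	nitrate_reductase	FULL
NPKS	NADH_GOGAT	FULL
NPKS	fatty_acid_desaturase	PARTIAL
NPKS	arachin_biosynthesis	PARTIAL
PK	Pi_translocator	NOT_DOWNREGULATED
PK	GBSS	FULL
PK	PGM	FULL
PK	glucosyltransferase	NOT_DOWNREGULATED
PK	ACCase	PARTIAL
PK	GAR_synthase_transformylase	NOT_DOWNREGULATED
PK	nitrate_reductase	FULL
PK	NADH_GOGAT	NOT_DOWNREGULATED
PK	fatty_acid_desaturase	PARTIAL
PK	arachin_biosynthesis	PARTIAL
NS	Pi_translocator	NOT_DOWNREGULATED
NS	GBSS	NOT_DOWNREGULATED
NS	PGM	NOT_DOWNREGULATED
NS	glucosyltransferase	PARTIAL
NS	ACCase	PARTIAL
NS	GAR_synthase_transformylase	PARTIAL
NS	nitrate_reductase	PARTIAL
NS	NADH_GOGAT	FULL
NS	fatty_acid_desaturase	NOT_DOWNREGULATED
NS	arachin_biosynthesis	NOT_DOWNREGULATED
PN	Pi_translocator	NOT_DOWNREGULATED
PN	GBSS	NOT_DOWNREGULATED
PN	PGM	NOT_DOWNREGULATED
PN	glucosyltransferase	PARTIAL
PN	ACCase	PARTIAL
PN	GAR_synthase_transformylase	PARTIAL
PN	nitrate_reductase	PARTIAL
PN	NADH_GOGAT	FULL
PN	fatty_acid_desaturase	NOT_DOWNREGULATED
PN	arachin_biosynthesis	NOT_DOWNREGULATED
PS	Pi_translocator	NOT_DOWNREGULATED
PS	GBSS	NOT_DOWNREGULATED
PS	PGM	NOT_DOWNREGULATED
PS	glucosyltransferase	NOT_DOWNREGULATED
PS	ACCase	PARTIAL
PS	GAR_synthase_transformylase	PARTIAL
PS	nitrate_reductase	NOT_DOWNREGULATED
PS	NADH_GOGAT	FULL
PS	fatty_acid_desaturase	PARTIAL
PS	arachin_biosynthesis	PARTIAL
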
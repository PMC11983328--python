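cui	name	entity_type	aliases
CD0000	DISEASE0000	DISEASE	DISEASE0000|DISEASE0000 syndrome|DSIEASE0000
CD0001	DISEASE0001	DISEASE	DISEASE0001|DISEASE0001 syndrome|DSIEASE0001
CD0002	DISEASE0002	DISEASE	DISEASE0002|DISEASE0002 syndrome|DSIEASE0002
CD0003	DISEASE0003	DISEASE	DISEASE0003|DISEASE0003 syndrome|DSIEASE0003
CD0004	DISEASE0004	DISEASE	DISEASE0004|DISEASE0004 syndrome|DSIEASE0004
CG0000	GENE0000	GENE	GENE0000|GENE0000 protein|GNEE0000
CG0001	GENE0001	GENE	GENE0001|GENE0001 protein|GNEE0001
CG0002	GENE0002	GENE	GENE0002|GENE0002 protein|GNEE0002
CG0003	GENE0003	GENE	GENE0003|GENE0003 protein|GNEE0003
CG0004	GENE0004	GENE	GENE0004|GENE0004 protein|GNEE0004
CG0005	GENE0005	GENE	GENE0005|GENE0005 protein|GNEE0005
CG0006	GENE0006	GENE	GENE0006|GENE0006 protein|GNEE0006
CG0007	GENE0007	GENE	GENE0007|GENE0007 protein|GNEE0007
CG0008	GENE0008	GENE	GENE0008|GENE0008 protein|GNEE0008
CG0009	GENE0009	GENE	GENE0009|GENE0009 protein|GNEE0009
CG0010	GENE0010	GENE	GENE0010|GENE0010 protein|GNEE0010
CG0011	GENE0011	GENE	GENE0011|GENE0011 protein|GNEE0011
CG0012	GENE0012	GENE	GENE0012|GENE0012 protein|GNEE0012
CG0013	GENE0013	GENE	GENE0013|GENE0013 protein|GNEE0013
CG0014	GENE0014	GENE	GENE0014|GENE0014 protein|GNEE0014
CG0015	GENE0015	GENE	GENE0015|GENE0015 protein|GNEE0015
CG0016	GENE0016	GENE	GENE0016|GENE0016 protein|GNEE0016
CG0017	GENE0017	GENE	GENE0017|GENE0017 protein|GNEE0017
CG0018	GENE0018	GENE	GENE0018|GENE0018 protein|GNEE0018
CG0019	GENE0019	GENE	GENE0019|GENE0019 protein|GNEE0019
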
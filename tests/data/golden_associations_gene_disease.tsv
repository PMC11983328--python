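type_x	type_y	cui_x	name_x	cui_y	name_y	count	score	p_value	p_adj
GENE	DISEASE	CG0000	GENE0000	CD0000	DISEASE0000	11	6.903264642677537	4.1581740397719484e-06	0.00027028131258517664
GENE	DISEASE	CG0002	GENE0002	CD0002	DISEASE0002	8	5.564230756915534	0.00019430984549797663	0.00631506997868424
GENE	DISEASE	CG0013	GENE0013	CD0003	DISEASE0003	3	3.4251838292579029	0.018029446815054008	0.39063801432617012
GENE	DISEASE	CG0003	GENE0003	CD0004	DISEASE0004	4	3.3668621393372775	0.047245904749244616	0.76774595217522501
GENE	DISEASE	CG0011	GENE0011	CD0003	DISEASE0003	3	2.7382220635685708	0.10830710525553368	0.9265031550363616
GENE	DISEASE	CG0003	GENE0003	CD0001	DISEASE0001	4	2.6614378682509572	0.28615832794511992	0.9265031550363616
GENE	DISEASE	CG0016	GENE0016	CD0001	DISEASE0001	3	2.6338412408907645	0.13476120080887097	0.9265031550363616
GENE	DISEASE	CG0007	GENE0007	CD0003	DISEASE0003	2	2.5619350808900139	0.082612539883904199	0.9265031550363616
GENE	DISEASE	CG0019	GENE0019	CD0000	DISEASE0000	2	2.389350350369301	0.11494252873563218	0.9265031550363616
GENE	DISEASE	CG0015	GENE0015	CD0001	DISEASE0001	3	2.3475459349520529	0.27003902912653255	0.9265031550363616
GENE	DISEASE	CG0009	GENE0009	CD0004	DISEASE0004	2	2.2213006136686442	0.16999365272041342	0.9265031550363616
GENE	DISEASE	CG0016	GENE0016	CD0004	DISEASE0004	2	2.2213006136686442	0.16999365272041342	0.9265031550363616
GENE	DISEASE	CG0001	GENE0001	CD0001	DISEASE0001	3	2.1470892313700647	0.41704392368596876	0.9265031550363616
GENE	DISEASE	CG0018	GENE0018	CD0001	DISEASE0001	2	2.065070288047989	0.2274915173991951	0.9265031550363616
GENE	DISEASE	CG0014	GENE0014	CD0002	DISEASE0002	2	2.0068787973620159	0.25621076101625301	0.9265031550363616
GENE	DISEASE	CG0008	GENE0008	CD0003	DISEASE0003	2	1.9415837222145753	0.29317778142923084	0.9265031550363616
GENE	DISEASE	CG0009	GENE0009	CD0000	DISEASE0000	2	1.8107889546260867	0.378916852705459	0.9265031550363616
GENE	DISEASE	CG0008	GENE0008	CD0001	DISEASE0001	2	1.755894160593843	0.42152201396141359	0.9265031550363616
GENE	DISEASE	CG0004	GENE0004	CD0002	DISEASE0002	1	1.7470894675105513	0.24786324786324784	0.9265031550363616
GENE	DISEASE	CG0006	GENE0006	CD0004	DISEASE0004	1	1.723557762828579	0.24093722369584439	0.9265031550363616
GENE	DISEASE	CG0005	GENE0005	CD0002	DISEASE0002	2	1.7064149252946246	0.46347655773345814	0.9265031550363616
GENE	DISEASE	CG0011	GENE0011	CD0001	DISEASE0001	2	1.6508956328857924	0.51039203173121084	0.9265031550363616
GENE	DISEASE	CG0015	GENE0015	CD0000	DISEASE0000	2	1.6139584206870756	0.54233436976799798	0.9265031550363616
GENE	DISEASE	CG0001	GENE0001	CD0003	DISEASE0003	2	1.5827656720723418	0.56828456960318452	0.9265031550363616
GENE	DISEASE	CG0015	GENE0015	CD0002	DISEASE0002	2	1.5209297200700358	0.63576959450068538	0.9265031550363616
GENE	DISEASE	CG0010	GENE0010	CD0003	DISEASE0003	1	1.5065190528523991	0.32802829354553492	0.9265031550363616
GENE	DISEASE	CG0001	GENE0001	CD0000	DISEASE0000	2	1.4761426787616976	0.67566364559608805	0.9265031550363616
GENE	DISEASE	CG0006	GENE0006	CD0000	DISEASE0000	1	1.4050324122656568	0.3831417624521074	0.9265031550363616
GENE	DISEASE	CG0001	GENE0001	CD0002	DISEASE0002	2	1.3910576892288833	0.76363510338673313	0.9265031550363616
GENE	DISEASE	CG0010	GENE0010	CD0001	DISEASE0001	1	1.3624382906906907	0.40981432360742703	0.9265031550363616
GENE	DISEASE	CG0012	GENE0012	CD0004	DISEASE0004	1	1.3062125272284384	0.42679469981608381	0.9265031550363616
GENE	DISEASE	CG0003	GENE0003	CD0002	DISEASE0002	2	1.2932206858048327	0.85209679219581635	0.93081907827488042
GENE	DISEASE	CG0000	GENE0000	CD0001	DISEASE0001	2	1.2170889825418567	0.90820963056040638	0.94542363671912077
GENE	DISEASE	CG0000	GENE0000	CD0002	DISEASE0002	2	1.1827927057509433	0.93087865769267286	0.94542363671912077
GENE	DISEASE	CG0007	GENE0007	CD0001	DISEASE0001	1	1.1584581176917534	0.5483796563256832	0.9265031550363616
GENE	DISEASE	CG0014	GENE0014	CD0003	DISEASE0003	1	1.1417279430859675	0.55191634951754887	0.9265031550363616
GENE	DISEASE	CG0017	GENE0017	CD0003	DISEASE0003	1	1.1417279430859675	0.55191634951754887	0.9265031550363616
GENE	DISEASE	CG0018	GENE0018	CD0003	DISEASE0003	1	1.1417279430859675	0.55191634951754887	0.9265031550363616
GENE	DISEASE	CG0019	GENE0019	CD0002	DISEASE0002	1	1.1258139964935974	0.57814938684503892	0.9265031550363616
GENE	DISEASE	CG0005	GENE0005	CD0004	DISEASE0004	1	1.1106503068343221	0.56946194820256735	0.9265031550363616
GENE	DISEASE	CG0008	GENE0008	CD0004	DISEASE0004	1	1.1106503068343221	0.56946194820256735	0.9265031550363616
GENE	DISEASE	CG0012	GENE0012	CD0000	DISEASE0000	1	1.0648154518775617	0.62310949788263759	0.9265031550363616
GENE	DISEASE	CG0014	GENE0014	CD0000	DISEASE0000	1	1.0648154518775617	0.62310949788263759	0.9265031550363616
GENE	DISEASE	CG0017	GENE0017	CD0000	DISEASE0000	1	1.0648154518775617	0.62310949788263759	0.9265031550363616
GENE	DISEASE	CG0011	GENE0011	CD0004	DISEASE0004	1	1.0442359125996159	0.62764276601303126	0.9265031550363616
GENE	DISEASE	CG0012	GENE0012	CD0001	DISEASE0001	1	1.0325351440239945	0.65534236930117951	0.9265031550363616
GENE	DISEASE	CG0013	GENE0013	CD0001	DISEASE0001	1	1.0325351440239945	0.65534236930117951	0.9265031550363616
GENE	DISEASE	CG0017	GENE0017	CD0001	DISEASE0001	1	1.0325351440239945	0.65534236930117951	0.9265031550363616
GENE	DISEASE	CG0012	GENE0012	CD0002	DISEASE0002	1	1.003439398681008	0.68546226212130101	0.9265031550363616
GENE	DISEASE	CG0017	GENE0017	CD0002	DISEASE0002	1	1.003439398681008	0.68546226212130101	0.9265031550363616
GENE	DISEASE	CG0018	GENE0018	CD0002	DISEASE0002	1	1.003439398681008	0.68546226212130101	0.9265031550363616
GENE	DISEASE	CG0005	GENE0005	CD0003	DISEASE0003	1	0.97079186110728766	0.70359068253483881	0.9265031550363616
GENE	DISEASE	CG0009	GENE0009	CD0003	DISEASE0003	1	0.97079186110728766	0.70359068253483881	0.9265031550363616
GENE	DISEASE	CG0001	GENE0001	CD0004	DISEASE0004	1	0.90539447731304334	0.76119068417057612	0.9265031550363616
GENE	DISEASE	CG0002	GENE0002	CD0004	DISEASE0004	1	0.90539447731304334	0.76119068417057612	0.9265031550363616
GENE	DISEASE	CG0005	GENE0005	CD0000	DISEASE0000	1	0.90539447731304334	0.77200745225896605	0.9265031550363616
GENE	DISEASE	CG0005	GENE0005	CD0001	DISEASE0001	1	0.87794708029692159	0.8009286282863165	0.9265031550363616
GENE	DISEASE	CG0015	GENE0015	CD0003	DISEASE0003	1	0.86526797889162099	0.80554966151548391	0.9265031550363616
GENE	DISEASE	CG0008	GENE0008	CD0002	DISEASE0002	1	0.85320746264731229	0.82672589218629189	0.9265031550363616
GENE	DISEASE	CG0009	GENE0009	CD0002	DISEASE0002	1	0.85320746264731229	0.82672589218629189	0.9265031550363616
GENE	DISEASE	CG0016	GENE0016	CD0002	DISEASE0002	1	0.85320746264731229	0.82672589218629189	0.9265031550363616
GENE	DISEASE	CG0011	GENE0011	CD0002	DISEASE0002	1	0.8021875723726094	0.87199570413762106	0.93081907827488042
GENE	DISEASE	CG0002	GENE0002	CD0003	DISEASE0003	1	0.79138283603617088	0.87353790422719546	0.93081907827488042
GENE	DISEASE	CG0003	GENE0003	CD0003	DISEASE0003	1	0.73572265325688868	0.91849427613302759	0.94542363671912077
GENE	DISEASE	CG0003	GENE0003	CD0000	DISEASE0000	1	0.68616070424520126	0.95265885931587158	0.95265885931587158
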
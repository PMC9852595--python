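gene_id	weight
SYNUP001	1
SYNUP002	1
SYNUP003	1
SYNUP004	1
SYNUP005	1
SYNUP006	1
SYNUP007	1
SYNUP008	1
SYNUP009	1
SYNUP010	1
SYNUP011	1
SYNUP012	1
SYNUP013	1
SYNUP014	1
SYNUP015	1
SYNUP016	1
SYNUP017	1
SYNUP018	1
SYNUP019	1
SYNUP020	1
SYNUP021	1
SYNUP022	1
SYNUP023	1
SYNUP024	1
SYNUP025	1
SYNUP026	1
SYNUP027	1
SYNUP028	1
SYNUP029	1
SYNUP030	1
SYNUP031	1
SYNUP032	1
SYNUP033	1
SYNUP034	1
SYNUP035	1
SYNUP036	1
SYNUP037	1
SYNUP038	1
SYNUP039	1
SYNUP040	1
SYNUP041	1
SYNUP042	1
SYNUP043	1
SYNUP044	1
SYNUP045	1
SYNUP046	1
SYNUP047	1
SYNUP048	1
SYNUP049	1
SYNUP050	1
SYNUP051	1
SYNUP052	1
SYNUP053	1
SYNUP054	1
SYNUP055	1
SYNUP056	1
SYNUP057	1
SYNUP058	1
SYNUP059	1
SYNUP060	1
SYNUP061	1
SYNUP062	1
SYNUP063	1
SYNUP064	1
SYNUP065	1
SYNUP066	1
SYNUP067	1
SYNUP068	1
SYNUP069	1
SYNUP070	1
SYNUP071	1
SYNUP072	1
SYNUP073	1
SYNUP074	1
SYNUP075	1
SYNUP076	1
SYNUP077	1
SYNUP078	1
SYNUP079	1
SYNUP080	1
SYNUP081	1
SYNUP082	1
SYNUP083	1
SYNUP084	1
SYNUP085	1
SYNUP086	1
SYNUP087	1
SYNUP088	1
SYNUP089	1
SYNUP090	1
SYNUP091	1
SYNUP092	1
SYNUP093	1
SYNUP094	1
SYNUP095	1
SYNUP096	1
SYNUP097	1
SYNUP098	1
SYNUP099	1
SYNUP100	1
SYNUP101	1
SYNUP102	1
SYNUP103	1
SYNUP104	1
SYNUP105	1
SYNUP106	1
SYNUP107	1
SYNUP108	1
SYNUP109	1
SYNUP110	1
SYNUP111	1
SYNUP112	1
SYNUP113	1
SYNUP114	1
SYNUP115	1
SYNUP116	1
SYNUP117	1
SYNUP118	1
SYNUP119	1
SYNUP120	1
SYNUP121	1
SYNUP122	1
SYNDN001	-1
SYNDN002	-1
SYNDN003	-1
SYNDN004	-1
SYNDN005	-1
SYNDN006	-1
SYNDN007	-1
SYNDN008	-1
SYNDN009	-1
SYNDN010	-1
SYNDN011	-1
SYNDN012	-1
SYNDN013	-1
SYNDN014	-1
SYNDN015	-1
SYNDN016	-1
SYNDN017	-1
SYNDN018	-1
SYNDN019	-1
SYNDN020	-1
SYNDN021	-1
SYNDN022	-1
SYNDN023	-1
SYNDN024	-1
SYNDN025	-1
SYNDN026	-1
SYNDN027	-1
SYNDN028	-1
SYNDN029	-1
SYNDN030	-1
SYNDN031	-1
SYNDN032	-1
SYNDN033	-1
SYNDN034	-1
SYNDN035	-1
SYNDN036	-1
SYNDN037	-1
SYNDN038	-1
SYNDN039	-1
SYNDN040	-1
SYNDN041	-1
SYNDN042	-1
SYNDN043	-1
SYNDN044	-1
SYNDN045	-1
SYNDN046	-1
SYNDN047	-1
SYNDN048	-1
SYNDN049	-1
SYNDN050	-1
SYNDN051	-1
SYNDN052	-1
SYNDN053	-1
SYNDN054	-1
SYNDN055	-1
SYNDN056	-1
SYNDN057	-1
SYNDN058	-1
SYNDN059	-1
SYNDN060	-1
SYNDN061	-1
SYNDN062	-1
SYNDN063	-1
SYNDN064	-1
SYNDN065	-1
SYNDN066	-1
SYNDN067	-1
SYNDN068	-1
SYNDN069	-1
SYNDN070	-1
SYNDN071	-1
SYNDN072	-1
SYNDN073	-1
SYNDN074	-1
SYNDN075	-1
SYNDN076	-1
SYNDN077	-1
SYNDN078	-1
SYNDN079	-1
SYNDN080	-1
SYNDN081	-1
SYNDN082	-1
SYNDN083	-1
SYNDN084	-1
SYNDN085	-1
SYNDN086	-1
SYNDN087	-1
SYNDN088	-1
SYNDN089	-1
SYNDN090	-1
SYNDN091	-1
SYNDN092	-1
SYNDN093	-1
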
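residue	pos1	pos2	pos3	pos4	pos5	pos6	pos7	pos8	pos9	pos10	pos11
A	0.254448	0.041938	0.617606	0.150631	0.47813	0.337776	0.250677	0.393673	0.494345	0.729174	0.54065
C	0.38878	0.41883	0.175934	0.670993	0.160861	0.282025	0.840857	0.097343	0.204025	0.572263	0.329721
D	0.651275	0.287218	0.143733	0.443355	0.225556	0.596886	0.285071	0.323099	0.531191	0.197207	0.516379
E	0.614618	0.606464	0.321083	0.493671	0.053453	0.195938	0.087797	0.015636	0.47767	0.502523	0.292654
F	0.239753	0.659424	0.713143	0.380847	0.395472	0.362865	0.075007	0.123578	0.482795	0.333745	0.478425
G	0.675044	0.041629	0.684325	0.398285	0.379183	0.24506	0.322001	0.245203	0.648788	0.695751	0.165215
H	0.584255	0.455176	0.327469	0.295488	0.368455	0.278324	0.504398	0.147164	0.090424	0.714169	0.179262
I	0.747184	0.871462	0.672173	0.686322	0.361935	0.557058	0.527106	0.414329	0.144994	0.556248	0.055972
K	0.247827	0.802695	0.272732	0.210528	0.553204	0.726811	0.220067	0.454237	0.455272	0.038323	0.349118
L	0.722422	0.569931	0.574777	0.338612	0.141002	0.294992	0.662032	0.335631	0.603992	0.332827	0.938437
M	0.391767	0.01128	0.454047	0.358768	0.241547	0.357198	0.39097	0.354085	0.1407	0.611431	0.674682
N	0.222148	0.116463	0.645043	0.687842	0.369801	0.28544	0.503708	0.493339	0.347529	0.559341	0.398615
P	0.169625	0.583319	0.357018	0.222568	0.186567	0.261171	0.242747	0.22921	0.344257	0.105951	0.262458
Q	0.134832	0.376961	0.199803	0.162813	0.258593	0.248436	0.411888	0.180802	0.051254	0.310944	0.470831
R	0.670351	0.281588	0.241423	0.273167	0.379355	0.782375	0.414334	0.458934	0.094696	0.183743	0.489033
S	0.116302	0.20642	0.348724	0.103446	0.52247	0.388091	0.484339	0.303493	0.529089	0.112808	0.406782
T	0.182933	0.199292	0.122423	0.177034	0.013905	0.194789	0.386986	0.425856	0.39708	0.456685	0.387816
V	0.290862	0.114571	0.206198	0.578812	0.241352	0.292	0.05229	0.472661	0.212296	0.028403	0.637873
W	0.543115	0.182505	0.802964	0.212983	0.040174	0.358336	0.363016	0.284966	0.414191	0.167043	0.356677
Y	0.229405	0.346061	0.310684	0.387215	0.190452	0.267456	0.21644	0.218728	0.213986	0.33249	0.21899
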
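,VIP1,E23,PV23,SST23,VIP23,E4,PV4,SST4,VIP4,E5,PV5,SST5,VIP5,E6,PV6,SST6,VIP6
VIP1,0.0,0.0,0.0,0.15994837929406977,0.0,0.0,0.0,0.11170276308727006,0.0,0.0,0.0,0.09052729184110793,0.0,0.0,0.0,0.0699131613251406,0.0
E23,0.0831535127926343,0.10693744595677983,0.3293520270383636,0.22534176000367243,0.15310997809855278,0.01055089377986417,0.0,0.0,0.0,0.17027349100008343,0.048015680558019753,0.0,0.0,0.0974789061674619,0.036846219593386936,0.0,0.0
PV23,0.0,0.36696679680012717,0.21952651095685605,0.057327786588945565,0.10638221821001366,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
SST23,0.08874142334642754,0.2592521181819951,0.22811914598329378,0.04527675325154218,0.2662283682830085,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
VIP23,0.0,0.04680369932395015,0.08005309472129929,0.2678192032124503,0.044017420267777996,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
E4,0.03810433254791084,0.13845112880290575,0.0,0.0,0.0,0.11657954257200417,0.2750012320632594,0.20299503802572347,0.14647309514831047,0.0879465838674468,0.0,0.0,0.0,0.08286525591223547,0.0,0.0,0.0
PV4,0.0,0.0,0.0,0.0,0.0,0.39930443890174694,0.24840278648804726,0.054097023717726025,0.11491801461146652,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
SST4,0.0,0.0,0.0,0.0,0.0,0.24674660089590889,0.18007008829899407,0.05120005198777199,0.2748804594557165,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
VIP4,0.0,0.0,0.0,0.0,0.0,0.04985343697188957,0.0902543635311576,0.2742647459028087,0.05317195182248187,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
E5,0.06890162054737943,0.018195025827093047,0.12331658714441149,0.09570170221828907,0.0,0.010708252721015664,0.15047622596577667,0.08721983698773439,0.0,0.11542439262181678,0.26712596395340177,0.20862672296403392,0.13845749519015788,0.022527795702359868,0.12669219610686028,0.08946197593661957,0.0
PV5,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.36725307317942685,0.24727472616432308,0.046962544952846456,0.10731202382950134,0.0,0.0,0.0,0.0
SST5,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.25637980056388493,0.18270341495261344,0.050407984420619736,0.23794206857496933,0.0,0.0,0.0,0.0
VIP5,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.05429011708789794,0.08983590721283145,0.28031481570457367,0.04293750461797767,0.0,0.0,0.0,0.0
E6,0.0,0.01042027917498111,0.05946213356707108,0.0,0.0,0.029546275310031206,0.058342061772371195,0.0,0.0,0.010678653538021004,0.06471673489280899,0.0,0.0,0.10804042191993188,0.30942963281817987,0.17285308698127316,0.14461656261059283
PV6,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.39528970296514077,0.243489170259558,0.04865024448906222,0.09289033899123744
SST6,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.28009989864513135,0.18958892416783024,0.055186900149302755,0.2847223417592683
VIP6,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.05232091607602073,0.07465376071653759,0.2733288103850158,0.05097528309449994
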
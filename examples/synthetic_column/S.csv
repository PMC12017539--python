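,VIP1,E23,PV23,SST23,VIP23,E4,PV4,SST4,VIP4,E5,PV5,SST5,VIP5,E6,PV6,SST6,VIP6
VIP1,,0.1,0.10607924191500301,0.8779248772990558,0.1,0.1,0.1,0.5815840299950353,0.1,0.1,0.1,0.5469967377410384,0.10054557244031069,0.11377186832129452,0.1,0.44393414375083384,0.10934351930152808
E23,0.3858512415679299,0.5079459295735207,0.689590149361838,0.4661819416037107,0.35897981320378525,0.16940380644723682,0.10880832000208668,0.10456322175374347,0.1,0.8505700459708951,0.35206373096194293,0.10045862778715371,0.1,0.5872847387717586,0.26256174453984504,0.1,0.10867284430232063
PV23,0.1,1.41359167849995,1.0903565794469459,0.37972379602248246,0.5301586239375535,0.11103832767945859,0.10158814141171967,0.10438430685978071,0.1,0.1,0.1,0.10953570845496644,0.1,0.10603237296989619,0.11407369435746587,0.10256419588031557,0.11278914087913244
SST23,0.522516869256998,1.372305033132321,0.8137164969077658,0.33633090721480635,0.7854424287690702,0.1,0.10524886146820041,0.10595296863923483,0.10955029490488198,0.1,0.10543373401937613,0.1,0.1,0.10363857066437424,0.1,0.1,0.1
VIP23,0.11422351069451826,0.2861399197871293,0.3665476652780344,1.0598971231993408,0.32668976224596025,0.10564236459160521,0.1,0.10927514623515873,0.1,0.11213950882662636,0.10340216379488175,0.11210075352273208,0.10532248156121278,0.10959832159208507,0.1,0.1,0.10682603812971037
E4,0.2708047974463092,0.7310263773217587,0.1,0.1,0.10294149077722044,0.5350226922938912,0.73185550606398,0.5737350029158202,0.4396186144260985,0.5339109601114613,0.1,0.1,0.11126648730075046,0.5104351152789203,0.1108169582449496,0.1,0.1
PV4,0.11160414754916573,0.1,0.1,0.10902482951692866,0.1,1.5933606808327956,0.8809559643654056,0.4467555407493758,0.4341310473949331,0.11046015188296328,0.10197369093309522,0.1,0.10578498592807697,0.10941052366279368,0.11013840734615712,0.10614338893202678,0.1
SST4,0.1,0.1,0.1,0.1043182988516414,0.11483825268120565,1.1122313210184334,0.734319909066848,0.288523591024558,0.689327867737954,0.1,0.10553280227690023,0.10084860227728765,0.10482411044963019,0.10535268418305539,0.10290974677835307,0.1,0.10154876303488694
VIP4,0.1005627216735823,0.1,0.1,0.11054650231537422,0.11241495366264559,0.2865487825460559,0.3736175965864011,1.0934866889373838,0.3252907883213048,0.11231460287196221,0.10004768661819477,0.1029425214429186,0.10971663457171564,0.10091400893808444,0.10533074811029364,0.10278707223062855,0.10328530801698557
E5,0.42994898315204744,0.21304161051075293,0.9065178327906563,0.893404298972924,0.1,0.15981078350757294,1.1055047193663787,0.9195624683858821,0.1,0.5632965230438599,0.7216336277485403,0.5296767762244545,0.3827677911548949,0.17287825252374375,1.077606351042338,0.8320728873544448,0.10105555530923352
PV5,0.11314741017488493,0.11477645663304337,0.10438531096489888,0.1,0.10896722184990718,0.10160034735389199,0.10267037822162187,0.11487987450742676,0.1,1.343262843900169,0.8708307992802932,0.44987526325207683,0.5636198366054914,0.10617561568665548,0.1,0.1,0.10942617539813547
SST5,0.11170380684234658,0.10864069010172311,0.1078238090167824,0.1,0.10246870736676988,0.1,0.1,0.1,0.10098449421598571,1.1400303877269962,0.7538568947869648,0.2846699979211823,0.9080625743852648,0.1,0.1017626042821191,0.1,0.10666724445657301
VIP5,0.1,0.10520140938468817,0.10336162418589351,0.10718204073841398,0.1,0.1094139454057683,0.1,0.1,0.1,0.2843317831941058,0.4103058859013081,0.8659422185642655,0.3039354788031826,0.10934093127901785,0.1,0.1,0.1
E6,0.1,0.15054859043354943,0.4320774130878369,0.11426284943489917,0.1050745696734598,0.2752884829358967,0.46243913896323097,0.1,0.10276664975538011,0.1428407260304088,0.5407927293612378,0.1,0.10339999071983015,0.4677644827903975,0.7160679010952022,0.42838642321987225,0.3592142659564561
PV6,0.1,0.1059273225233453,0.10343756002996629,0.10611669418878672,0.10236688187597397,0.1,0.11342143883599079,0.1,0.1,0.1,0.10604811776719712,0.10054638045945836,0.1,1.4761667042847175,1.0890648242149816,0.4333660863712718,0.5476833254622602
SST6,0.11227038442148798,0.1,0.1,0.1,0.10697534696345667,0.1,0.11050078714050049,0.1,0.1,0.11180243577195668,0.10430772518580458,0.11100442885659796,0.11425889311882625,1.2230237978195009,0.790682427256081,0.257846527730645,0.8759267709263379
VIP6,0.10607133118147843,0.1,0.10005385309014643,0.11099639434507354,0.10154858826412741,0.1011112225824729,0.11491867837399404,0.1,0.1019966894705569,0.1,0.1,0.1,0.10018281615685726,0.3295953706864816,0.4205358208568002,0.9898470231348777,0.2921758222905078
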
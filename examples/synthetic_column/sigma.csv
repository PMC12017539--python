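,VIP1,E23,PV23,SST23,VIP23,E4,PV4,SST4,VIP4,E5,PV5,SST5,VIP5,E6,PV6,SST6,VIP6
VIP1,124.50279496151511,144.19457566815737,297.1398604106391,128.6359437003051,243.84068564458528,243.3344830327785,125.94301981211476,251.10735934370376,133.89982941014986,293.4836780281024,170.51854052653664,267.6258787663703,141.9494858155142,256.60077485056377,124.5332749688083,263.416222195121,236.47620215752522
E23,265.3062260858689,133.88565770069374,51.56132704541238,75.43301143988845,87.94047665138173,257.72825086412814,236.0477358587271,255.72750017661085,180.44542350939747,146.2178481819002,156.79267544634646,214.38175625212475,296.3141856369765,284.04712464244324,180.85433868299293,210.8869615428166,154.93734864222023
PV23,294.95415710428705,113.77602288493696,73.00579688034199,52.219524420343056,102.20932017637222,210.76037896021813,248.83128822817622,153.2671009380738,141.2100625047812,293.23563576025697,294.91618491375476,231.8353810675021,120.53844519311498,279.306851981724,232.39638241793347,177.0886901104238,142.14725643779317
SST23,157.7354654316327,95.58287375960725,85.55610769495894,87.1857237408137,107.15019514192358,212.34758231747912,292.12071574933657,298.20608892140524,209.74466525151337,189.81146217431575,180.70438572487845,136.55132377220426,286.2011400739894,224.31406127240106,255.79786742129784,258.34702733719837,282.98617405335546
VIP23,205.76021162237373,128.58386162739578,84.96409736803906,78.94860176761254,79.02673403922566,295.7333138074335,297.54289943487686,272.9786009828748,235.64706851513998,172.02529341615832,208.2989135830313,225.06826390812083,176.99958058857928,233.20691738429662,263.6508370643774,210.00417775068172,288.832516426991
E4,125.50074214894725,135.7344376311238,217.32528436778742,273.48737327022803,200.80442409412194,132.42445786977333,137.8040188427207,97.60851225872385,104.23322015516084,220.50961765361131,238.7929253963419,270.1512641373172,125.5279723980334,146.8016816472314,246.5874553327,177.44571381905652,151.20697624842765
PV4,187.3902062421736,166.54370615865054,185.82300094880088,257.3403956186796,180.98354483965528,98.47711156977377,132.37448899415568,145.06792040569164,71.48601496066809,211.53146601184244,243.84402839964358,220.21029524655947,280.1197919687887,167.7033005580294,255.98862012395705,191.1973669707237,206.15258514319808
SST4,179.34339601516385,158.35103007998683,297.1085927270648,163.85192509873377,203.73901979836893,53.12136847402621,144.6643378683717,90.80086304175408,138.13196005929396,238.15087557747654,222.05965813301333,243.38414674740943,171.95095668397772,277.2870090069863,149.99647153261904,292.0185246430684,223.99452059240338
VIP4,126.60722205407684,274.9949455114712,133.51839692115672,286.3540344404658,174.76524977021847,76.02360656075365,96.06188548997974,88.18634376005318,116.14080930880748,282.3114812478557,244.45242697370153,199.53130115588232,221.16831873077035,140.8411769797126,245.2646009457373,148.19769115027614,231.49597641514515
E5,206.35450733859597,155.1493494818066,240.32310044029015,251.61295623732443,154.25627249218482,236.6332105536701,162.3999638396067,140.14055172679917,178.69957406225592,113.69108491210326,109.27327558955346,51.03993441316962,70.32751528342622,142.1006261115513,206.69624189478026,261.4860977615252,150.22524914453226
PV5,238.29184812063392,133.03498917091142,122.00940445360094,210.19959510738022,265.2028772806402,147.65034821785773,151.14443062767748,208.17120575708094,224.87506443541733,86.48414565033204,74.2621437965627,148.3389067775517,80.45833589779326,151.3200368606481,265.9232443886891,221.47096356282415,225.86023746619128
SST5,120.97406168327691,179.6540776573854,232.19459892625218,193.15109664677323,281.50742383790003,250.4069260151306,218.3327024286825,255.04534881648775,220.04163574508868,139.8471409197848,136.1884380370293,105.64019267194064,105.31878527891493,295.08226308975225,217.54101631821374,276.31373080417416,214.95300558142796
VIP5,271.47828644813416,285.0326287620301,286.56560087975373,238.6829356630759,164.11072585133414,176.44611694899714,218.99591200532842,270.6619196733308,259.47512730089574,54.612912434426065,87.68657855556046,97.85495463650898,78.79071944250917,255.3357022252742,254.12562884512874,293.1777037468329,286.28779882651264
E6,277.2772473313024,244.23959336776807,289.3444102890741,295.1019847547844,206.05593762101705,137.09801792655557,151.15324479491355,152.86156848310637,188.87631457325222,245.2696001057036,261.2083479410188,152.8200673093478,193.15930650721725,135.4888743842164,134.35386747447893,53.55053481764309,107.1909792419323
PV6,216.76468136861365,150.4958573984036,168.30172955977108,234.73499924071226,181.91097808912048,207.36157213666382,147.81270351375997,178.35938832111248,195.52735017523662,247.7802212173179,178.31937710771766,220.20300392312964,284.9552508280308,120.24178610613775,118.1096331464511,135.70375931213883,124.76342825608347
SST6,282.69153372278697,263.667593015974,194.80367978579633,127.65667052061063,235.9477995432342,237.87167486840426,151.56969743184584,178.2444643987079,224.4528549637891,281.50665346412165,178.90649372640564,174.27132635129306,183.40133881730122,119.95914042375108,98.01058273634949,52.303996871323285,79.25812167690536
VIP6,280.4037166190697,249.75668806187429,132.03802784877124,238.29823937162882,177.199733222781,170.87780550654892,266.1330199193784,173.5363036166193,265.5598545010881,199.40017837768644,287.4705698199001,165.79149274774448,129.87340833709186,117.73069732401996,139.82274620384055,90.1376011642994,75.89751632224815
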
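provenance: synthetic
global:
  G: 5.0
  nmda_fraction: 0.2
  R: 125.0
  R0: 75.0
  Mg: 1.0
  dt: 0.1
fractions:
  VIP1: 0.016
  E23: 0.24649999999999997
  PV23: 0.020300000000000002
  SST23: 0.014499999999999999
  VIP23: 0.0087
  E4: 0.204
  PV4: 0.016800000000000002
  SST4: 0.012
  VIP4: 0.0072
  E5: 0.1955
  PV5: 0.016100000000000003
  SST5: 0.011500000000000002
  VIP5: 0.0069
  E6: 0.19039999999999999
  PV6: 0.015680000000000003
  SST6: 0.011200000000000002
  VIP6: 0.00672
groups:
  VIP1:
    V_rest: -68.77701590499922
    V_th: -50.23822003258264
    C_m: 96.7946018263533
    g_L: 7.662517366016759
    tau_ref: 1.5
    nu_bg: 1193.576975236454
  E23:
    V_rest: -69.94738740833846
    V_th: -49.99701679431305
    C_m: 204.31778675663742
    g_L: 9.849541865510398
    tau_ref: 2.0
    nu_bg: 1556.361977088385
  PV23:
    V_rest: -72.58563092669645
    V_th: -51.87594542440583
    C_m: 109.39815079480553
    g_L: 10.323676703537132
    tau_ref: 1.0
    nu_bg: 1803.6900160430048
  SST23:
    V_rest: -65.20108582783436
    V_th: -47.61470498246688
    C_m: 122.05743536838833
    g_L: 7.929026167092034
    tau_ref: 1.5
    nu_bg: 1236.0226605319533
  VIP23:
    V_rest: -67.1845187738116
    V_th: -50.84569111514225
    C_m: 94.65622518075863
    g_L: 6.889530852758548
    tau_ref: 1.5
    nu_bg: 953.7122517888707
  E4:
    V_rest: -69.74852592131782
    V_th: -50.844552830164524
    C_m: 195.1515278896166
    g_L: 9.591618872406487
    tau_ref: 2.0
    nu_bg: 1428.3881097879712
  PV4:
    V_rest: -71.53995866386626
    V_th: -51.771141043785434
    C_m: 100.64718879716314
    g_L: 10.850477695863175
    tau_ref: 1.0
    nu_bg: 1826.4874040314141
  SST4:
    V_rest: -64.88919124871957
    V_th: -47.754976277409106
    C_m: 117.85507309106319
    g_L: 7.589153594266424
    tau_ref: 1.5
    nu_bg: 1154.3801333903236
  VIP4:
    V_rest: -67.37377781623334
    V_th: -49.943522018058125
    C_m: 89.0909763554937
    g_L: 6.951613903743164
    tau_ref: 1.5
    nu_bg: 1032.826435006115
  E5:
    V_rest: -70.5122417729128
    V_th: -49.57901303831983
    C_m: 188.7169296524696
    g_L: 10.698097246915586
    tau_ref: 2.0
    nu_bg: 1771.5563984595312
  PV5:
    V_rest: -72.0046483979713
    V_th: -52.36197017831538
    C_m: 108.49751559041809
    g_L: 10.456133955687758
    tau_ref: 1.0
    nu_bg: 1734.0328210062944
  SST5:
    V_rest: -65.97385888190232
    V_th: -47.93912988934575
    C_m: 115.64260761856835
    g_L: 7.649427183082344
    tau_ref: 1.5
    nu_bg: 1211.058964243468
  VIP5:
    V_rest: -68.67133935693798
    V_th: -50.27229976805514
    C_m: 85.55066593311604
    g_L: 6.900880616770602
    tau_ref: 1.5
    nu_bg: 1067.4768033008409
  E6:
    V_rest: -69.79758845773645
    V_th: -49.919974572627765
    C_m: 208.3479287963113
    g_L: 10.4641716019999
    tau_ref: 2.0
    nu_bg: 1650.5733961971075
  PV6:
    V_rest: -72.63706882671784
    V_th: -52.13323941505741
    C_m: 99.33159679932797
    g_L: 9.989746803944877
    tau_ref: 1.0
    nu_bg: 1723.7231403941107
  SST6:
    V_rest: -65.00352866771169
    V_th: -46.318226811417595
    C_m: 120.7158664835747
    g_L: 8.446873797237433
    tau_ref: 1.5
    nu_bg: 1417.803608684496
  VIP6:
    V_rest: -67.44863360046337
    V_th: -50.958442343274214
    C_m: 89.19670323801695
    g_L: 6.516729426155619
    tau_ref: 1.5
    nu_bg: 907.5649723815533
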
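structure,metric,n,min_pct,max_pct,mean_pct,std_pct,p
Brainstem,D2,3,-1.612324,1.976045,0.058421,1.806879,0.960432
OpticChiasm,D2,3,-6.841953,9.232076,0.763619,8.071681,0.884903
OpticNerve_L,D2,3,-7.587661,21.082180,2.954233,15.768674,0.776358
OpticNerve_R,D2,3,-0.557396,22.968113,8.028242,12.986324,0.396360
PTV1,CI,3,-11.445783,11.144578,-1.104418,11.415358,0.882331
PTV1,D2,3,-0.987715,2.015572,0.333941,1.533662,0.742328
PTV1,D95,3,-3.954216,1.094053,-1.399694,2.524683,0.438254
PTV1,D98,3,-5.622574,-0.380494,-3.127707,2.630135,0.175613
PTV1,V95,3,-11.445783,11.144578,-1.104418,11.415358,0.882331
PTV2,CI,3,-10.169492,7.384988,-2.219532,8.893431,0.707691
PTV2,D2,3,-1.171465,1.844342,0.216983,1.522032,0.828000
PTV2,D95,3,-7.100430,-1.484419,-5.215827,3.231549,0.107679
PTV2,D98,3,-10.828485,-0.489351,-6.709147,5.480270,0.168056
PTV2,V95,3,-10.169492,7.384988,-2.219532,8.893431,0.707691
PTVnx,D2,3,-0.936502,2.114520,0.393689,1.562573,0.705145
PTVnx,D95,3,-2.019036,1.402414,-0.526275,1.751886,0.654709
PTVnx,D98,3,-2.605375,1.119619,-0.994617,1.912855,0.462848
PTVnx,HI,3,6.228663,10.364775,8.708761,2.187737,0.020394
Parotid_L,DMEAN,3,-31.881443,10.837854,-11.253053,21.397168,0.458498
Parotid_R,DMEAN,3,11.723520,99.371232,47.000769,46.256500,0.220489
SpinalCord,D2,3,-7.363815,103.742907,32.048083,62.191771,0.466282
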
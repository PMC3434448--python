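label,hemisphere,x,y,z,volume
L_Precentral,left,-42.3,-7.2,39.4,10167.0
L_Superior_Frontal,left,-17.2,36.9,36.7,13167.0
L_Middle_Frontal,left,-36.0,25.9,30.8,14783.0
L_Inferior_Frontal,left,-44.5,21.7,3.2,8191.5
L_Paracentral,left,-6.2,-31.5,52.7,2550.0
L_Medial_Frontal,left,-6.7,26.6,27.1,10794.0
L_Postcentral,left,-40.3,-27.2,47.1,8248.5
L_Superior_Parietal,left,-26.0,-58.3,52.2,3244.5
L_Inferior_Parietal,left,-48.1,-41.0,40.3,7582.5
L_Angular,left,-43.9,-66.9,33.9,505.5
L_Supramarginal,left,-54.6,-46.6,30.2,1203.0
L_Precuneus,left,-13.0,-61.5,41.1,11618.0
L_Superior_Occipital,left,-35.6,-81.1,26.3,528.0
L_Middle_Occipital,left,-35.1,-83.3,6.1,2749.5
L_Inferior_Occipital,left,-33.6,-85.5,-8.2,1213.5
L_Cuneus,left,-11.1,-82.9,18.7,8146.5
L_Lingual,left,-12.4,-77.3,-3.2,4962.0
L_Superior_Temporal,left,-51.7,-17.4,1.6,10010.0
L_Middle_Temporal,left,-55.3,-36.3,-1.1,9009.0
L_Inferior_Temporal,left,-53.9,-37.5,-14.3,2535.0
L_Transverse_Temporal,left,-50.6,-20.9,11.5,1332.0
L_Fusiform,left,-39.9,-49.1,-15.6,5530.5
L_Cingulate,left,-6.9,-7.8,35.6,6937.5
L_Anterior_Cingulate,left,-6.0,33.2,8.8,4252.5
L_Posterior_Cingulate,left,-8.0,-54.5,15.3,2754.0
L_Parahippocampal,left,-23.9,-25.0,-11.7,5001.0
R_Precentral,right,44.1,-7.0,39.3,10749.0
R_Superior_Frontal,right,19.2,38.0,35.2,14063.0
R_Middle_Frontal,right,37.3,26.1,31.6,15624.0
R_Inferior_Frontal,right,46.7,22.0,4.9,8244.0
R_Paracentral,right,6.8,-31.4,53.1,2776.5
R_Medial_Frontal,right,7.5,26.6,26.7,10829.0
R_Postcentral,right,41.9,-27.0,47.4,8149.5
R_Superior_Parietal,right,27.5,-58.3,52.6,3481.5
R_Inferior_Parietal,right,49.0,-40.8,40.5,6873.0
R_Angular,right,43.9,-65.3,34.2,582.0
R_Supramarginal,right,52.7,-45.0,31.1,1231.5
R_Precuneus,right,13.4,-61.6,40.6,12014.0
R_Superior_Occipital,right,36.3,-81.0,26.6,388.5
R_Middle_Occipital,right,35.3,-83.0,6.5,2755.5
R_Inferior_Occipital,right,33.4,-85.2,-8.3,1143.0
R_Cuneus,right,11.8,-82.6,19.5,7707.0
R_Lingual,right,13.1,-76.3,-3.1,4957.5
R_Superior_Temporal,right,52.0,-14.1,-0.3,9825.0
R_Middle_Temporal,right,55.6,-33.0,-2.8,8463.0
R_Inferior_Temporal,right,53.7,-35.0,-15.8,2460.0
R_Transverse_Temporal,right,52.7,-19.9,11.5,1287.0
R_Fusiform,right,40.8,-48.6,-15.6,5145.0
R_Cingulate,right,7.9,-8.5,36.0,7749.0
R_Anterior_Cingulate,right,6.9,34.0,8.5,4234.5
R_Posterior_Cingulate,right,9.0,-54.4,15.0,2706.0
R_Parahippocampal,right,24.3,-25.6,-11.2,4452.0
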
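region,fbp_ramp,fbp_butterworth,fbp_hamming,fbp_hanning,fbp_parzen,fbp_3drp,osem2d_iter1,osem2d_iter2,osem2d_iter3,osem2d_iter4,osem2d_iter5,osem2d_iter6,osem2d_iter7,osem2d_iter8,osem2d_iter9,osem2d_iter10,mapem_beta0.1,mapem_beta1.0,mapem_beta1.5
Tumor,-9.5,-35.4,-25.6,-21.8,-25.6,-5.4,-,1.5,8.7,11.4,16.7,20.4,22.8,25.7,28.6,32.4,4.4,12.8,-11.2
Adrenals,0.0,-25.9,-14.0,-15.9,35.7,-0.8,-,13.7,26.3,35.7,43.6,51.2,56.9,60.2,71.9,152.8,4.0,14.4,-7.7
Brain,21.7,-19.6,-16.9,-20.1,71.6,-10.8,-,33.0,55.7,71.6,83.8,96.8,98.7,103.1,109.5,169.6,-12.1,7.3,-23.8
Breasts,-2.7,-31.3,-17.6,-20.9,35.6,-5.6,-,12.7,25.9,35.6,42.6,53.5,56.3,57.7,70.2,152.1,-2.7,7.8,-11.4
Gallbladder wall,1.9,-22.2,-12.1,-13.2,33.3,3.7,-,14.2,25.0,33.3,40.3,49.5,52.6,57.1,67.1,150.5,4.7,16.6,-9.0
Lower large intestine wall,-3.2,-32.7,-20.7,-20.7,31.6,-3.2,-,11.8,22.2,31.6,40.0,49.4,52.9,57.8,69.4,151.3,6.1,17.1,-6.5
Small intestine,0.0,-24.7,-13.0,-15.8,32.7,0.0,-,13.6,23.7,32.7,40.8,48.1,53.6,58.6,68.8,151.3,4.8,15.7,-7.6
Stomach wall,4.8,-10.9,-6.4,-7.5,19.6,9.4,-,7.6,13.8,19.6,25.1,33.7,35.1,42.8,57.2,144.5,-1.7,-1.0,-8.8
Upper lower intestine wall,0.0,-24.4,-14.0,-14.0,31.2,2.2,-,12.2,23.1,31.2,40.0,47.9,51.6,57.4,67.6,150.7,4.3,14.1,-6.7
Heart wall,-2.4,-29.3,-17.7,-19.1,35.4,-2.4,-,12.0,26.3,35.4,42.9,53.0,55.5,57.3,70.2,151.9,0.0,8.9,-11.0
Kidneys,4.9,-20.9,-8.7,-13.6,39.3,3.8,-,16.8,29.4,39.3,47.8,45.2,61.3,66.7,76.7,154.7,1.7,12.0,-4.5
Liver,2.1,-21.3,-11.0,-11.8,33.8,5.8,-,14.6,25.2,33.8,40.3,50.6,52.4,57.0,64.8,149.8,6.9,20.1,-9.5
Lungs,-6.4,-35.2,-22.6,-24.1,37.6,-8.2,-,11.2,28.6,37.6,45.1,55.8,57.5,58.1,71.7,152.7,-7.0,1.1,-14.5
Muscle,0.0,-25.8,-15.4,-15.4,37.2,0.0,-,15.8,27.2,37.2,44.4,54.2,57.1,61.4,72.7,153.2,5.6,13.3,-5.9
Ovaries,-3.2,-32.7,-16.9,-20.7,33.8,0.0,-,14.5,24.7,33.8,42.0,51.2,56.2,60.9,70.7,152.2,9.0,19.7,-3.2
Pancreas,0.6,-24.8,-13.1,-14.5,33.2,-0.6,-,13.7,24.3,33.2,41.4,51.5,55.1,58.3,71.9,152.5,6.5,15.3,-5.7
Red. Marrow,0.0,-26.9,-14.1,-17.1,38.3,-2.7,-,14.6,29.2,38.3,48.0,56.6,60.6,64.3,75.4,154.5,2.6,12.3,-8.2
Osteogenic,0.0,-29.6,-17.5,-17.5,41.0,-3.3,-,14.9,30.1,41.0,48.8,59.1,62.2,65.2,77.2,155.1,0.0,12.1,-10.2
Skin,0.0,-26.7,-12.5,-19.4,38.1,0.0,-,16.2,30.0,38.1,45.5,55.3,61.2,64.0,74.1,154.1,5.7,11.1,-6.1
Spleen,-3.1,-34.5,-18.2,-19.0,37.2,-11.4,-,15.2,26.6,37.2,47.0,60.4,63.7,64.2,80.9,156.6,15.4,25.3,-0.7
Thymus,-5.1,-31.9,-19.2,-22.2,36.7,-5.1,-,11.8,28.0,36.7,44.7,54.5,57.1,58.4,71.0,152.4,-2.5,4.9,-13.3
Thyroid,0.0,-33.3,-24.0,-24.0,40.0,-7.4,-,13.3,30.3,40.0,48.6,60.0,63.4,63.4,75.6,154.8,-7.4,6.9,-15.4
Urinary bladder,-5.5,-38.3,-22.5,-24.0,34.5,-4.9,-,14.4,25.0,34.5,42.3,53.0,55.5,61.2,70.3,151.9,10.7,23.2,-3.6
Uterus,-3.9,-33.7,-21.3,-21.3,33.6,-3.9,-,14.3,25.2,33.6,42.4,52.5,55.6,60.4,70.0,152.0,9.2,20.7,-3.8
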
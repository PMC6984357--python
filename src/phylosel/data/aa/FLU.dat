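0.13865876
0.053366579 0.16100089
0.58485231 0.0067718425 7.7373929
0.026447095 0.16720701 1.3024986e-05 0.014132063
0.35375398 3.2927169 0.53064266 0.14546939 0.002547334
1.4842345 0.12489762 0.061652192 5.3705113 3.9110699e-11 1.1956291
1.1323131 1.1906245 0.32252465 1.9348328 0.11694146 0.10805134 1.5930988
0.21475786 1.8795699 1.387096 0.88757055 0.021844617 5.3303134 0.25649186 0.058774527
0.14992673 0.24611717 0.21857198 0.014085917 0.0011121581 0.02883995 0.014210712 1.6266228e-05 0.24319014
0.023116952 0.29604556 0.00083587317 0.0057306821 0.0056136272 1.020367 0.016499536 0.0065162294 0.32161169 3.5120723
0.47433361 15.300097 2.646848 0.29004298 3.8322812e-06 2.5595872 3.8814888 0.26414893 0.34730279 0.227708 0.12922364
0.058745423 0.89016235 0.0052516878 0.041762964 0.11145731 0.19025918 0.31397435 0.0015004669 0.0012735089 9.0179542 6.7469365 1.3312916
0.080490909 0.016055031 0.00083644562 1.0600103e-06 0.10405367 0.032680657 0.0010035008 0.001236645 0.11902851 1.4633573 2.9868 0.3198959 0.27991051
0.65931148 0.15402718 0.036441772 0.18853946 1.5931206e-13 0.7127696 0.31955883 0.038631761 0.92446691 0.080543327 0.63430852 0.19575063 0.056869322 0.0071324305
3.0113445 0.95013841 3.8813105 0.33837218 0.33626334 0.4878225 0.3071403 1.5856466 0.58070425 0.29038108 0.57076669 0.28380767 0.0070265883 0.99668567 2.0873853
5.4182982 0.18307691 2.1403323 0.13548123 0.011975266 0.60234096 0.2801249 0.01880803 0.36871357 2.9040523 0.044926357 1.5269642 2.0315113 0.00013490624 0.54225109 2.2068599
0.19596635 1.3694294 0.00053628404 1.4893874e-05 0.09410668 0.04402052 0.15524549 0.19648645 0.022372919 0.03213215 0.43127766 4.9764145e-05 0.070460039 0.81475309 0.0004310207 0.099835753 0.20706621
0.018289288 0.099855497 0.37310193 0.52539854 0.60169243 0.072205935 0.10409287 0.074814997 6.4489544 0.27393426 0.34005847 0.012416222 0.87427217 5.3939242 0.00018229488 0.39255224 0.12489802 0.42775543
3.5320053 0.10396439 0.010257517 0.29712398 0.054904564 0.40669781 0.28504795 0.33722962 0.098631355 14.394052 0.89059858 0.07312793 4.9048422 0.59258799 0.058971975 0.088256423 0.65410911 0.25690046 0.16758165

0.047071805 0.050910205 0.074214307 0.047859605 0.025021603 0.033303603 0.054587405 0.076373408 0.019964202 0.067133607 0.071498107 0.056784506 0.018150702 0.030496103 0.050656105 0.088409109 0.074338607 0.018523702 0.031474103 0.063229206
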
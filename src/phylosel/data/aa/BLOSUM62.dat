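0.73579039
0.48539106 1.2974467
0.54316182 0.50096441 3.1801
1.4599953 0.22782657 0.39735895 0.24083661
1.1997057 3.0208336 1.8392161 1.1909457 0.3298015
1.170949 1.3605742 1.2404885 3.7616252 0.14074889 5.5289192
1.9558836 0.41876331 1.3558723 0.79847325 0.41820319 0.60984631 0.42357999
0.71624144 1.4561412 2.4145014 0.77814266 0.35405811 2.4353411 1.6268911 0.53985912
0.605899 0.23203645 0.28301733 0.41855573 0.77489402 0.23620245 0.18684805 0.18929629 0.25271845
0.80001653 0.62271167 0.21188816 0.21813158 0.83184264 0.58073709 0.37262518 0.21772116 0.34807221 3.8909638
1.2952013 5.4111151 1.593137 1.0324479 0.2850788 3.9452777 2.8024272 0.75204244 1.022507 0.40619359 0.44557027
1.2537583 0.98369299 0.64844128 0.2226219 0.76768882 2.4948961 0.5554154 0.45943617 0.98431153 3.3647978 6.0305594 1.0730612
0.49296468 0.37164469 0.35486125 0.28173069 0.44133747 0.14435696 0.29140908 0.36816646 0.7145337 1.5173593 2.0648397 0.26692475 1.7738552
1.1732759 0.44813366 0.49488704 0.73062827 0.3560085 0.85857058 0.92656393 0.5040866 0.52700734 0.38835541 0.37455569 1.0473835 0.45412363 0.23359791
4.3250927 1.1227831 2.9041017 1.5827541 1.1971884 1.9348709 1.7698932 1.5093263 1.1170298 0.35754441 0.35296918 1.7521659 0.91872342 0.54002764 1.1691296
1.729178 0.91466595 1.8981736 0.93418751 1.1198314 1.2774803 1.0710972 0.64143601 0.58540709 1.1790912 0.91525986 1.3038752 1.4885481 0.48820612 1.0054517 5.1515563
0.46583937 0.42638231 0.19148205 0.14534505 0.52766442 0.75865381 0.40763565 0.50835892 0.3012486 0.34198579 0.69147463 0.33224304 0.8881011 2.0743249 0.25221483 0.38792562 0.51312813
0.7182067 0.72051744 0.53822252 0.26142221 0.47023773 0.95898974 0.5967193 0.30805574 4.218954 0.67461709 0.81124586 0.71799349 0.95168216 6.7472604 0.36940532 0.79675152 0.80101024 4.054419
2.1877745 0.43838834 0.3128588 0.25812929 1.1163525 0.53078579 0.52425385 0.25334079 0.20155597 8.3118394 2.2314057 0.49813848 2.5758508 0.83811961 0.49690841 0.56192546 2.2530741 0.26650873 1

0.074 0.052 0.045 0.054 0.025 0.034 0.054 0.074 0.026 0.068 0.099 0.058 0.025 0.047 0.039 0.057 0.051 0.013 0.032 0.073
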
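0.531678
0.557967 0.451095
0.827445 0.154899 5.54953
0.574478 1.019843 0.313311 0.105625
0.556725 3.021995 0.768834 0.521646 0.091304
1.066681 0.318483 0.578115 7.766557 0.053907 3.417706
1.740159 1.359652 0.773313 1.272434 0.546389 0.231294 1.115632
0.21997 3.210671 4.025778 1.032342 0.724998 5.68408 0.243768 0.201696
0.361684 0.239195 0.491003 0.115968 0.150559 0.07827 0.111773 0.053769 0.181788
0.310007 0.372261 0.137289 0.061486 0.164593 0.709004 0.097485 0.069492 0.540571 2.335139
0.369437 6.529255 2.529517 0.282466 0.049009 2.966732 1.731684 0.26984 0.525096 0.202562 0.146481
0.469395 0.431045 0.33072 0.190001 0.409202 0.456901 0.175084 0.130379 0.32966 4.831666 3.856906 0.624581
0.138293 0.065314 0.073481 0.032522 0.678335 0.045683 0.043829 0.050212 0.453428 0.77709 2.500294 0.024521 0.436181
1.959599 0.710489 0.121804 0.127164 0.123653 1.608126 0.191994 0.208081 1.141961 0.09858 1.060504 0.216345 0.164215 0.148483
3.887095 1.001551 5.057964 0.589268 2.155331 0.548807 0.312449 1.874296 0.743458 0.405119 0.592511 0.474478 0.285564 0.943971 2.788406
4.582565 0.650282 2.351311 0.425159 0.469823 0.523825 0.331584 0.316862 0.477355 2.553806 0.272514 0.965641 2.114728 0.138904 1.176961 4.777647
0.084329 1.257961 0.0277 0.057466 1.104181 0.172206 0.114381 0.54418 0.128193 0.13451 0.530324 0.089134 0.201334 0.537922 0.069965 0.310927 0.080556
0.139492 0.235601 0.700693 0.453952 2.114852 0.254745 0.063452 0.0525 5.8484 0.303445 0.241094 0.087904 0.18987 5.484236 0.11385 0.628608 0.201094 0.747889
2.924161 0.171995 0.164525 0.315261 0.621323 0.179771 0.465271 0.47014 0.121827 9.533943 1.761439 0.124066 3.038533 0.593478 0.211561 0.408532 1.14398 0.239697 0.165473

0.076861923 0.051056949 0.042545957 0.051268949 0.02027898 0.041060959 0.061819938 0.074713925 0.022982977 0.052568947 0.091110909 0.059497941 0.023413977 0.040529959 0.050531949 0.068224932 0.058517941 0.014335986 0.032302968 0.066373934
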
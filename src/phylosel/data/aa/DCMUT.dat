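0.267828
0.984474 0.327059
1.199805 0 8.931515
0.360016 0.232374 0 0
0.887753 2.439939 1.028509 1.348551 0
1.961167 0 1.493409 11.388659 0 7.086022
2.386111 0.087791 1.385352 1.240981 0.107278 0.281581 0.811907
0.228116 2.383148 5.290024 0.868241 0.282729 6.011613 0.439469 0.106802
0.653416 0.632629 0.768024 0.239248 0.438074 0.180393 0.609526 0 0.076981
0.406431 0.154924 0.341113 0 0 0.730772 0.11288 0.071514 0.443504 2.556685
0.258635 4.610124 3.148371 0.716913 0 1.519078 0.830078 0.267683 0.270475 0.460857 0.180629
0.71784 0.896321 0 0 0 1.127499 0.304803 0.170372 0 3.332732 5.230115 2.411739
0.183641 0.136906 0.138503 0 0 0 0 0.153478 0.475927 1.951951 1.56516 0 0.92186
2.48592 1.028313 0.419244 0.13394 0.18755 1.526188 0.507003 0.347153 0.933709 0.119152 0.316258 0.335419 0.170205 0.110506
4.05187 1.53159 4.885892 0.956097 1.598356 0.561828 0.793999 2.322243 0.353643 0.247955 0.171432 0.954557 0.619951 0.459901 2.427202
3.680365 0.265745 2.271697 0.66093 0.162366 0.525651 0.340156 0.306662 0.226333 1.900739 0.33109 1.350599 1.031534 0.136655 0.782857 5.436674
0 2.001375 0.224968 0 0 0 0 0 0.270564 0 0.461776 0 0 0.762354 0 0.740819 0
0.244139 0.078012 0.94694 0 0.953164 0 0.214717 0 1.2654 0.374834 0.286572 0.132142 0 6.952629 0 0.336289 0.417839 0.60807
2.059564 0.240368 0.158067 0.178316 0.484678 0.346983 0.36725 0.538165 0.438715 8.810038 1.745156 0.10385 2.565955 0.123606 0.485026 0.303836 1.561997 0 0.279379

0.087126913 0.040903959 0.04043196 0.046871953 0.033473967 0.038254962 0.04952995 0.088611911 0.033618966 0.036885963 0.085356915 0.08048092 0.014752985 0.03977196 0.050679949 0.06957693 0.058541941 0.01049399 0.02991597 0.064717935
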
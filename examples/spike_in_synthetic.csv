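,sc0,sc1,sc2,sc3,sc4,sc5,sc6,sc7,sc8,sc9,sc10,sc11,sc12,sc13,sc14,sc15,sc16,sc17,sc18,sc19,sc20,sc21,sc22,sc23,sc24,sc25,sc26,sc27,sc28,sc29,sc30,sc31,sc32,sc33,sc34,sc35,sc36,sc37,sc38,sc39,sc40,sc41,sc42,sc43,sc44,sc45,sc46,sc47,sc48,sc49,sc50,sc51,sc52,sc53,sc54,sc55,sc56,sc57,sc58,sc59,sc60,sc61,sc62,sc63,sc64,sc65,sc66,sc67,sc68,sc69,sc70,sc71,sc72,sc73,sc74,sc75,sc76,sc77,sc78,sc79
KLF1,4.4779,5.7698,2.0723,5.9671,4.0225,3.1784,3.1751,2.8612,3.8248,5.0108,4.7306,4.7914,2.1749,2.3138,5.8181,5.1622,6.524,5.4324,2.9268,5.517,4.7803,4.3165,3.1561,4.0787,3.9107,5.0765,4.2152,5.8528,3.207,4.6039,4.635,3.1062,2.7508,5.2123,4.6559,3.8933,4.5179,3.3182,4.3429,3.3969,4.2873,5.1815,3.6947,5.0286,2.9158,3.752,2.5451,3.9628,4.1638,3.8544,3.7754,5.5786,5.6723,2.7123,5.3923,2.1432,3.2519,3.8811,4.2001,2.9009,3.2654,4.1615,3.2979,3.3565,4.8228,5.1205,4.0082,4.096,4.0536,3.5659,3.5021,2.9118,4.8027,3.9812,3.9214,4.3005,4.6707,5.6692,3.7688,3.6257
GATA2,4.8898,2.4736,2.6652,2.9545,5.251,4.2056,4.6711,4.361,5.094,4.1503,3.6823,5.0657,2.0621,2.1575,3.3084,4.2801,0.0,3.5896,3.7511,4.024,3.5222,4.635,4.166,5.6519,4.2571,2.609,4.1116,2.8811,4.7504,5.6513,4.9002,3.7345,4.0686,4.0132,4.5553,4.8541,5.4552,3.9467,4.2777,4.4861,4.8174,3.621,4.2762,4.4871,4.6116,5.1779,3.538,5.5432,3.7857,4.0059,4.4136,2.7031,2.6158,3.5488,3.0148,1.9261,3.2458,4.3081,5.6063,3.5582,4.5563,5.2618,4.1484,4.7976,4.6344,4.5371,4.5222,4.089,4.3157,4.3675,4.9125,3.7616,4.3189,4.7672,5.4538,4.5357,5.4801,2.4923,4.4724,5.1814
FLI1,4.4893,4.0212,4.8527,4.1136,4.7578,4.9025,3.1807,4.6344,3.4055,4.241,4.7073,3.1888,5.5148,5.5505,5.3039,5.4979,4.7401,2.9886,4.0323,4.641,4.7459,4.6779,5.2352,3.5815,4.1232,3.8551,5.5325,4.6387,2.7178,2.4409,3.4179,6.382,5.2644,2.4802,3.9185,4.2133,4.4606,4.8578,3.5022,4.5722,3.2928,2.1042,3.4253,3.3152,5.1197,5.0105,3.5165,3.9291,4.6735,2.7808,1.7964,4.8659,5.1403,4.0265,1.8077,5.0001,4.1778,3.1972,3.3506,3.4108,4.7,3.7936,3.6844,4.2583,3.9793,2.3331,3.9143,3.8429,2.2179,3.4295,4.3756,3.8765,5.8185,5.893,3.3932,4.7046,6.0198,4.6189,3.0805,3.3179
RUNX1,2.6186,4.7104,4.9275,5.2826,3.4534,4.0825,2.6672,3.322,3.0307,4.0459,4.3126,3.9405,4.7225,5.0554,6.2061,5.2277,4.8078,4.572,3.9432,4.8898,5.8245,3.0461,3.4145,3.3733,4.8899,6.6813,3.4968,5.477,2.5811,4.0808,4.0701,3.923,3.3093,4.9861,4.7524,2.8204,3.1935,4.1278,4.1564,3.7479,2.862,4.6986,2.2299,4.2478,4.0536,1.5962,3.8123,3.8352,4.4804,2.7595,4.6144,4.6066,6.7603,3.8471,5.0389,4.8643,4.6011,4.3415,3.6368,4.197,4.3859,3.874,4.0204,3.3151,3.929,4.1245,4.2361,4.5915,3.9903,4.451,2.9917,4.4577,4.955,2.659,2.9506,5.1325,2.7709,6.6161,2.854,3.415
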
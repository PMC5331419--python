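compound_id,pic50_pred,ad_flag
CID_44421999,6.32,Y
CID_44422008,6.49,Y
CID_44422014,6.53,Y
CID_44422020,6.47,Y
CID_44422031,6.34,Y
CID_44422034,6.15,Y
CID_44422037,6.14,Y
CID_44422041,6.07,Y
CID_44422043,5.82,Y
CID_44422044,5.67,Y
CID_44422045,5.62,Y
CID_44422047,6.69,N
CID_44422053,6.16,Y
CID_44422054,6.91,Y
CID_44422058,6.90,Y
CID_44422064,6.12,Y
CID_44422067,5.94,Y
CID_44422075,6.25,Y
CID_44422080,6.33,Y
CID_44433644,6.53,Y
CID_44433645,6.20,Y
CID_67854257,7.51,N
CID_69758112,6.69,Y
CID_70126216,7.35,N
CID_70126231,7.17,Y
CID_70126247,6.91,Y
CID_70126297,5.60,Y
CID_70126298,5.83,Y
CID_70126305,6.56,Y
CID_70126327,7.42,N
CID_70126491,6.40,Y
CID_70126782,6.27,Y
CID_70126784,6.24,Y
CID_70126798,6.48,N
CID_70126802,6.87,N
CID_70126837,6.36,Y
CID_70126868,6.75,N
CID_70126881,7.90,N
CID_70126979,6.39,Y
CID_70126991,6.89,Y
CID_70127144,6.82,Y
CID_70127147,7.76,N
CID_70127181,6.03,Y
CID_70127183,6.35,Y
CID_70127185,6.87,N
CID_70127188,6.96,N
CID_70127192,6.88,Y
CID_70127194,6.81,Y
CID_70127269,6.35,Y
CID_70127287,7.48,N
CID_70127296,6.92,N
CID_70127297,6.77,Y
CID_70127298,6.82,Y
CID_70127444,6.80,Y
CID_70127446,7.54,N
CID_70127567,5.89,Y
CID_70127714,7.00,N
CID_70127721,6.57,Y
CID_70127722,6.82,Y
CID_70127760,6.91,N
CID_70127771,6.66,Y
CID_70127818,7.06,N
CID_70127821,7.17,N
CID_70128062,6.59,Y
CID_70128068,7.19,N
CID_70128078,6.06,Y
CID_70128083,6.83,Y
CID_70128084,6.81,Y
CID_70128209,6.75,Y
CID_70128238,6.83,Y
CID_70128450,6.33,Y
CID_70128452,7.23,N
CID_70128456,6.71,Y
CID_70128462,6.84,Y
CID_70128533,6.79,Y
CID_70128534,6.92,Y
CID_70128574,7.18,N
CID_70128608,7.18,N
CID_70128824,7.37,Y
CID_70128828,6.46,Y
CID_70128830,7.00,Y
CID_70128847,7.46,N
CID_70128902,6.50,Y
CID_70128904,6.57,Y
CID_70128987,5.60,Y
CID_70129065,6.69,N
CID_70129161,7.05,Y
CID_70129198,6.53,Y
CID_70129204,7.14,N
CID_70129375,6.18,Y
CID_70129377,6.74,Y
CID_70129380,7.12,Y
CID_9804916,6.38,Y
CID_9826776,6.33,Y
CID_9827285,6.48,Y
CID_9828392,6.12,Y
CID_9828587,6.86,N
CID_9829426,6.45,Y
CID_9891033,6.14,Y
CID_9893352,5.94,Y
CID_9933226,6.34,Y
CID_9935104,6.56,Y
CID_9935196,6.57,Y
CID_9935788,6.50,Y
CID_9936347,6.45,Y
CID_9936803,6.36,Y
CID_9955874,6.20,Y
CID_9957122,6.62,Y
CID_9957692,6.57,Y
CID_9958161,6.19,Y
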
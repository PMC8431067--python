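country,outcome,measure,estimate,se,stars
Germany,postponed,cci,0.0096,0.0243,
Germany,postponed,hi,0.0227,0.0242,
Germany,denied,cci,-0.0136,0.0096,
Germany,denied,hi,-0.0007,0.0099,
Sweden,postponed,cci,-0.1085,0.0258,***
Sweden,postponed,hi,0.0003,0.0525,
Sweden,denied,cci,-0.0325,0.0195,*
Sweden,denied,hi,-0.0116,0.0214,
Spain,postponed,cci,-0.0290,0.0661,
Spain,postponed,hi,-0.0019,0.0677,
Spain,denied,cci,0.0052,0.0177,
Spain,denied,hi,0.0233,0.0365,
Italy,postponed,cci,-0.0046,0.0274,
Italy,postponed,hi,0.0485,0.0275,*
Italy,denied,cci,-0.0409,0.0143,**
Italy,denied,hi,-0.0277,0.0139,**
France,postponed,cci,0.0066,0.0379,
France,postponed,hi,0.0469,0.0389,
France,denied,cci,0.0128,0.0197,
France,denied,hi,0.0223,0.0198,
Denmark,postponed,cci,-0.0071,0.0278,
Denmark,postponed,hi,-0.0307,0.0338,
Denmark,denied,cci,0.0000,0.0136,
Denmark,denied,hi,0.0040,0.0175,
Greece,postponed,cci,-0.0355,0.0160,**
Greece,postponed,hi,-0.0206,0.0163,
Greece,denied,cci,-0.0321,0.0113,**
Greece,denied,hi,-0.0263,0.0106,**
Switzerland,postponed,cci,-0.0414,0.0435,
Switzerland,postponed,hi,-0.0311,0.0425,
Switzerland,denied,cci,-0.0182,0.0127,
Switzerland,denied,hi,-0.0054,0.0243,
Belgium,postponed,cci,-0.0449,0.0277,
Belgium,postponed,hi,0.0186,0.0266,
Belgium,denied,cci,-0.0099,0.0148,
Belgium,denied,hi,0.0034,0.0153,
Czech Republic,postponed,cci,-0.0309,0.0613,
Czech Republic,postponed,hi,-0.0333,0.0673,
Czech Republic,denied,cci,-0.0191,0.0211,
Czech Republic,denied,hi,-0.0017,0.0681,
Poland,postponed,cci,-0.0231,0.0239,
Poland,postponed,hi,-0.0055,0.0242,
Poland,denied,cci,-0.0381,0.0130,**
Poland,denied,hi,-0.0343,0.0135,**
Luxembourg,postponed,cci,-0.0653,0.0683,
Luxembourg,postponed,hi,-0.0255,0.0691,
Luxembourg,denied,cci,-0.0006,0.0229,
Luxembourg,denied,hi,-0.0032,0.0225,
Hungary,postponed,cci,-0.0378,0.0721,
Hungary,postponed,hi,0.0487,0.0724,
Hungary,denied,cci,-0.0169,0.0289,
Hungary,denied,hi,0.0128,0.0728,
Portugal,postponed,cci,0.0330,0.1325,
Portugal,postponed,hi,0.0240,0.0934,
Portugal,denied,cci,-0.0468,0.0591,
Portugal,denied,hi,-0.0221,0.0595,
Slovenia,postponed,cci,0.0093,0.0324,
Slovenia,postponed,hi,0.0353,0.0313,
Slovenia,denied,cci,-0.0032,0.0099,
Slovenia,denied,hi,0.0044,0.0124,
Estonia,postponed,cci,0.0445,0.0220,**
Estonia,postponed,hi,0.0739,0.0247,***
Estonia,denied,cci,-0.0034,0.0148,
Estonia,denied,hi,0.0045,0.0144,
Croatia,postponed,cci,-0.0062,0.0274,
Croatia,postponed,hi,0.0399,0.0278,
Croatia,denied,cci,-0.0088,0.0106,
Croatia,denied,hi,-0.0035,0.0125,
Lithuania,postponed,cci,-0.0142,0.0332,
Lithuania,postponed,hi,0.0171,0.0373,
Lithuania,denied,cci,0.0030,0.0239,
Lithuania,denied,hi,0.0321,0.0263,
Bulgaria,postponed,cci,0.0094,0.0150,
Bulgaria,postponed,hi,-0.0333,0.0421,
Bulgaria,denied,cci,0.0149,0.0114,
Bulgaria,denied,hi,0.0117,0.0475,
Cyprus,postponed,cci,-0.0164,0.0421,
Cyprus,postponed,hi,-0.0066,0.0437,
Cyprus,denied,cci,0.0112,0.0182,
Cyprus,denied,hi,0.0229,0.2060,
Finland,postponed,cci,0.0287,0.0366,
Finland,postponed,hi,0.0337,0.0381,
Finland,denied,cci,-0.0148,0.0208,
Finland,denied,hi,-0.0155,0.0210,
Latvia,postponed,cci,0.0296,0.0298,
Latvia,postponed,hi,0.0513,0.0360,
Latvia,denied,cci,0.0317,0.0235,
Latvia,denied,hi,0.0405,0.0262,
Malta,postponed,cci,-0.0658,0.0480,
Malta,postponed,hi,0.0183,0.0549,
Malta,denied,cci,-0.0168,0.0104,
Malta,denied,hi,-0.0097,0.1025,
Romania,postponed,cci,0.0318,0.0201,
Romania,postponed,hi,0.0352,0.0190,*
Romania,denied,cci,-0.0024,0.0192,
Romania,denied,hi,0.0013,0.0218,
Slovakia,postponed,cci,-0.0557,0.0364,
Slovakia,postponed,hi,0.0429,0.0430,
Slovakia,denied,cci,0.0007,0.0148,
Slovakia,denied,hi,-0.0010,0.0171,
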
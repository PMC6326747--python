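,ROI001,ROI002,ROI003,ROI004,ROI005,ROI006,ROI007,ROI008,ROI009,ROI010
ROI001,1.0,0.04425161879435209,0.0836704840866808,0.04191261001301274,0.04669462866370115,0.19038074590584084,0.2874342247800113,0.13884163824166454,0.1511057470448148,0.10689414165824414
ROI002,0.04425161879435209,1.0,0.018663121056443903,0.029161996965014897,0.0649037877690721,0.22814928092472675,0.121717648361377,0.17870266602802143,0.09232945984789556,0.16204883983253016
ROI003,0.0836704840866808,0.018663121056443903,1.0,0.02129251622792506,0.05116902761564872,0.11437718221146903,0.0733600729080489,0.10701156550985086,0.037387150206601764,-0.003465380468886136
ROI004,0.04191261001301274,0.029161996965014897,0.02129251622792506,1.0,-0.0030214539577471614,0.0732661854412247,-0.024523132268446803,0.11252458389792197,0.009648964536324049,0.07475975663737222
ROI005,0.04669462866370115,0.0649037877690721,0.05116902761564872,-0.0030214539577471614,1.0,0.05381367948395124,0.25821743841971145,0.056850470835951905,0.09244962200616365,0.03870973163869308
ROI006,0.19038074590584084,0.22814928092472675,0.11437718221146903,0.0732661854412247,0.05381367948395124,1.0,0.4058288497724354,0.8181178517864288,0.44915503355018904,0.3630018661258557
ROI007,0.2874342247800113,0.121717648361377,0.0733600729080489,-0.024523132268446803,0.25821743841971145,0.4058288497724354,1.0,0.367956481775278,0.40083052500793526,0.327932023693026
ROI008,0.13884163824166454,0.17870266602802143,0.10701156550985086,0.11252458389792197,0.056850470835951905,0.8181178517864288,0.367956481775278,1.0,0.4179214602080933,0.3939738649284044
ROI009,0.1511057470448148,0.09232945984789556,0.037387150206601764,0.009648964536324049,0.09244962200616365,0.44915503355018904,0.40083052500793526,0.4179214602080933,1.0,0.30285980850571254
ROI010,0.10689414165824414,0.16204883983253016,-0.003465380468886136,0.07475975663737222,0.03870973163869308,0.3630018661258557,0.327932023693026,0.3939738649284044,0.30285980850571254,1.0
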
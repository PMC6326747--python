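roi,w,I
ROI001,0.2018905338179353,0.26221959313907545
ROI002,0.2596966874469234,0.2570566228630611
ROI003,0.3264489409434685,0.26774656352809995
ROI004,0.3511706523472029,0.2721112542990823
ROI005,0.5086598389301544,0.301142438271046
ROI006,0.5638444232543262,0.30404002976542877
ROI007,0.5902373148939654,0.3253004046377741
ROI008,0.6924602195575889,0.3178266788076756
ROI009,0.7436443912259139,0.34103791629828445
ROI010,0.777847086543038,0.33438520423997864
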
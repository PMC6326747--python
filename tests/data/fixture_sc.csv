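,ROI001,ROI002,ROI003,ROI004,ROI005,ROI006,ROI007,ROI008,ROI009,ROI010
ROI001,0.0,0.07490782533050097,0.09092285115460427,0.085636754587661,0.04981104126708067,0.09976438876505704,0.13432069354506598,0.0,0.02430866799761741,0.0
ROI002,0.07490782533050097,0.0,0.050053293685282094,0.19907645526452336,0.028296578975476983,0.1374871454336909,0.0,0.0158048101175097,0.0,0.05815811956631968
ROI003,0.09092285115460427,0.050053293685282094,0.0,0.10856180792972057,0.03094898503891316,0.018204888823497273,0.0,0.03454675434438749,0.0,0.0
ROI004,0.085636754587661,0.19907645526452336,0.10856180792972057,0.0,0.015890810141494172,0.0,0.0,0.04091662163690237,0.02448960247299868,0.0
ROI005,0.04981104126708067,0.028296578975476983,0.03094898503891316,0.015890810141494172,0.0,0.0,0.13495566169853607,0.0,0.0,0.0
ROI006,0.09976438876505704,0.1374871454336909,0.018204888823497273,0.0,0.0,0.0,0.052915705065527605,0.17944202082812555,0.10029954698303861,0.0161784336236114
ROI007,0.13432069354506598,0.0,0.0,0.0,0.13495566169853607,0.052915705065527605,0.0,0.025012238619433316,0.2,0.16308855693873586
ROI008,0.0,0.0158048101175097,0.03454675434438749,0.04091662163690237,0.0,0.17944202082812555,0.025012238619433316,0.0,0.043566345672580054,0.08255622145233968
ROI009,0.02430866799761741,0.0,0.0,0.02448960247299868,0.0,0.10029954698303861,0.2,0.043566345672580054,0.0,0.12903734824492563
ROI010,0.0,0.05815811956631968,0.0,0.0,0.0,0.0161784336236114,0.16308855693873586,0.08255622145233968,0.12903734824492563,0.0
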
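domain,level,decrement
mobility,1,0.0
mobility,2,0.1
mobility,3,0.3
self_care,1,0.0
self_care,2,0.1
self_care,3,0.25
usual_activities,1,0.0
usual_activities,2,0.08
usual_activities,3,0.2
pain_discomfort,1,0.0
pain_discomfort,2,0.12
pain_discomfort,3,0.32
anxiety_depression,1,0.0
anxiety_depression,2,0.1
anxiety_depression,3,0.28
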
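location,year,song_type_tag,recording_id,date,duration_min,migration_stage
STB,2016,,X,2 July,55,northbound
STB,2016,,Y,5 July,55,northbound
STB,2016,,Z,21 July,60,northbound
Cook Strait,2016,,X,10 July,60,northbound
Cook Strait,2016,,Y,22 July,40,northbound
Cook Strait,2016,,Z,9 Aug,85,northbound
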
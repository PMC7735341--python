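location,year,song_type_tag,recording_id,date,duration_min,migration_stage
New Caledonia,2015,A,X,17 July,48,breeding ground
New Caledonia,2015,A,Y,18 July,32,breeding ground
New Caledonia,2015,A,Z,23 Aug,47,breeding ground
New Caledonia,2015,B,X,5 Aug,45,breeding ground
New Caledonia,2015,B,Y,6 Aug,51,breeding ground
New Caledonia,2015,B,Z,18 Aug,52,breeding ground
New Caledonia,2016,,X,25 July (a.m.),60,breeding ground
New Caledonia,2016,,Y,25 July (p.m.),55,breeding ground
New Caledonia,2016,,Z,28 July,55,breeding ground
New Caledonia,2017,,X,5 Aug,53,breeding ground
New Caledonia,2017,,Y,24 Aug,45,breeding ground
New Caledonia,2017,,Z,29 Aug,52,breeding ground
East Australia,2015,,X,18 July,30,end of northbound migration
East Australia,2015,,Y,23 July,40,end of northbound migration
East Australia,2015,,Z,17 Sep,44,start of southbound migration
East Australia,2016,,X,25 Sep,40,start of southbound migration
East Australia,2016,,Y,27 Sep,50,start of southbound migration
East Australia,2016,,Z,19 Oct,51,start of southbound migration
East Australia,2017,,X,6 July,41,end of northbound migration
East Australia,2017,,Y,17 July,44,end of northbound migration
East Australia,2017,,Z,18 July,44,end of northbound migration
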
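location,year,recording_id,song_type_tag,themes
New Zealand,2016,,,1 2 3 4 5
New Zealand,2016,,9Aug,5 6 7 8
New Caledonia,2015,,A,12 13 14 15 16
New Caledonia,2015,,B,5 6 8
New Caledonia,2016,,,1 2 3 4 5 6 8
New Caledonia,2017,,,3 9 10 11
East Australia,2015,,northbound,5 6 8
East Australia,2015,,southbound,1 2 3 4 5
East Australia,2016,,southbound,3 9 10 11
East Australia,2017,,northbound,3 9 10 11
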
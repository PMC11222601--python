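case_id,score_dsa,score_combined
bl001,5,5
bl002,5,5
bl003,5,5
bl004,5,5
bl005,5,5
bl006,5,5
bl007,5,5
bl008,5,5
bl009,5,5
bl010,5,5
bl011,5,5
bl012,5,5
bl013,5,5
bl014,5,5
bl015,5,5
bl016,5,5
bl017,5,5
bl018,5,5
bl019,5,5
bl020,5,5
bl021,5,5
bl022,5,5
bl023,5,5
bl024,5,5
bl025,5,5
bl026,5,5
bl027,5,5
bl028,5,5
bl029,5,5
bl030,5,5
bl031,5,5
bl032,5,5
bl033,5,5
bl034,5,5
bl035,5,5
bl036,5,5
bl037,5,5
bl038,5,5
bl039,5,5
bl040,5,5
bl041,5,5
bl042,5,5
bl043,5,5
bl044,5,5
bl045,5,5
bl046,5,5
bl047,4,5
bl048,4,5
bl049,4,5
bl050,4,5
bl051,4,5
bl052,4,5
bl053,4,5
bl054,4,5
bl055,4,5
bl056,4,5
bl057,4,5
bl058,4,5
bl059,4,5
bl060,4,5
bl061,4,5
bl062,4,5
bl063,4,5
bl064,4,5
bl065,4,5
bl066,4,5
bl067,4,5
bl068,4,5
bl069,4,5
bl070,4,5
bl071,4,5
bl072,4,5
bl073,4,5
bl074,4,5
bl075,4,4
bl076,4,4
bl077,4,4
bl078,4,4
bl079,4,4
bl080,4,4
bl081,4,4
bl082,4,4
bl083,4,4
bl084,4,4
bl085,4,4
bl086,4,4
bl087,4,4
bl088,4,4
bl089,4,4
bl090,4,4
bl091,4,4
bl092,4,4
bl093,4,4
bl094,4,4
bl095,3,4
bl096,3,4
bl097,3,4
bl098,3,4
bl099,3,4
bl100,3,4
bl101,3,4
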
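case_id,score_dsa,score_combined
nb001,1,1
nb002,1,1
nb003,1,1
nb004,1,1
nb005,1,1
nb006,1,1
nb007,1,1
nb008,1,1
nb009,1,1
nb010,1,1
nb011,1,1
nb012,1,1
nb013,1,1
nb014,1,1
nb015,1,1
nb016,1,1
nb017,1,1
nb018,1,1
nb019,1,1
nb020,1,1
nb021,1,1
nb022,2,1
nb023,2,1
nb024,2,1
nb025,2,1
nb026,2,1
nb027,2,1
nb028,2,1
nb029,2,1
nb030,2,1
nb031,2,1
nb032,2,1
nb033,2,1
nb034,2,1
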
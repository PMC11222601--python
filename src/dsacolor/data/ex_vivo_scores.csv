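case_id,score_dsa,score_combined
ev001,5,5
ev002,5,5
ev003,5,5
ev004,5,5
ev005,5,5
ev006,5,5
ev007,5,5
ev008,5,5
ev009,5,5
ev010,5,5
ev011,5,5
ev012,4,5
ev013,4,5
ev014,4,5
ev015,4,5
ev016,4,5
ev017,4,5
ev018,4,5
ev019,4,3
ev020,4,3
ev021,3,5
ev022,3,4
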
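"""Published descriptive reference values the calibrated simulation targets.

These are the study-level descriptive statistics for international women's
rugby sevens match play that the default synthetic study is calibrated to
reproduce: per-record means of contacts, playing time, RPE and sRPE, the
number of complete records after listwise deletion, the twelve zone-distance
means, and the adjusted share of sRPE variance the workload model explains.
They are used only as comparison targets in reports; no computation reads
them as inputs.
"""

#: Mean distance (m) per player-match in each speed x acceleration zone.
ZONE_DISTANCE_REFERENCE_M = {
    "LS_LA": 11.24,
    "LS_HA": 1.99,
    "LS_LD": 259.39,
    "LS_HD": 2.85,
    "MS_LA": 21.67,
    "MS_HA": 16.82,
    "MS_LD": 703.58,
    "MS_HD": 16.41,
    "HS_LA": 2.37,
    "HS_HA": 2.60,
    "HS_LD": 82.49,
    "HS_HD": 1.78,
}

SUMMARY_REFERENCE = {
    "contacts_mean": 4.0,
    "playing_time_min_mean": 11.8,
    "rpe_mean": 7.0,
    "srpe_mean": 99.2,
    "complete_records": 1002,
    "r2_adjusted": 0.487,
}
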
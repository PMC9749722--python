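"""Published counts from the nationwide Brazilian cohort evaluation of the
Bolsa Família Programme (registrants 2011–2015, followed to end 2015).

These printed counts are the inputs of the package's worked examples:
balance (SMD) reproduction, recipient shares, cause-of-death shares, the
crude CVD rate, and the e-value of the fifth-deprivation-quintile
premature all-cause hazard ratio. The underlying person-level data are
restricted; only these aggregates are public.
"""

#: 30–69-year ("premature mortality") study population
PREMATURE = {
    "n_total": 4_855_324,
    "n_non_recipient": 1_677_485,
    "n_recipient": 3_177_839,
    "men_non_recipient": 753_821,
    "men_recipient": 1_577_715,
    "urban_non_recipient": 1_490_072,
    "urban_recipient": 2_705_036,
}

#: all-age (0–100 years) study population
ALL_AGE = {
    "n_total": 17_981_582,
    "n_non_recipient": 4_276_248,
    "n_recipient": 13_705_334,
    "men_non_recipient": 2_011_476,
    "men_recipient": 6_686_079,
}

#: all-age death counts and person-time
DEATHS = {
    "all_cause": 106_807,
    "cvd": 23_389,
    "ihd": 7_471,
    "cerebrovascular": 6_722,
    "person_years": 47_869_832,
}

#: premature all-cause hazard ratio in the most deprived (fifth) quintile,
#: the estimate with the largest reported e-value
FIFTH_QUINTILE_PREMATURE_ALL_CAUSE = {"hr": 0.82, "ci": (0.78, 0.87)}
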
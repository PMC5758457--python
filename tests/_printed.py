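"""Published baseline outcome cells used by the acceptance tests.

Only cells that are arithmetically consistent with the decision tree are
listed.  Omitted as internally inconsistent with their own neighbouring
printed columns (documented in the project notes): the >42 CS-TI rate cells,
the >42 SOC live-birth cell, the 38-40 delta cells, the whole CS-TI IUI-cost
column (and hence CS-TI totals and total/IUI deltas), and the >42 CS-TI IVF
cost cells.
"""

# (column, age band) -> published percent value
RATE_CELLS = {
    ("soc_pregnancy", "<35"): 92.88,
    ("soc_pregnancy", "35-37"): 88.97,
    ("soc_pregnancy", "38-40"): 78.43,
    ("soc_pregnancy", "41-42"): 62.17,
    ("soc_pregnancy", ">42"): 38.97,
    ("cs_ti_pregnancy", "<35"): 94.22,
    ("cs_ti_pregnancy", "35-37"): 91.80,
    ("cs_ti_pregnancy", "38-40"): 84.93,
    ("cs_ti_pregnancy", "41-42"): 77.60,
    ("delta_pregnancy", "<35"): 1.34,
    ("delta_pregnancy", "35-37"): 2.83,
    ("delta_pregnancy", "41-42"): 15.43,
    ("soc_live_birth", "<35"): 68.54,
    ("soc_live_birth", "35-37"): 61.90,
    ("soc_live_birth", "38-40"): 50.81,
    ("soc_live_birth", "41-42"): 33.23,
    ("cs_ti_live_birth", "<35"): 66.16,
    ("cs_ti_live_birth", "35-37"): 58.72,
    ("cs_ti_live_birth", "38-40"): 49.42,
    ("cs_ti_live_birth", "41-42"): 35.99,
    ("delta_live_birth", "<35"): -2.38,
    ("delta_live_birth", "35-37"): -3.18,
    ("delta_live_birth", "41-42"): 2.76,
}

# (column, age band) -> published dollar value
COST_CELLS = {
    ("soc_iui_cost", "<35"): 6484,
    ("soc_iui_cost", "35-37"): 6657,
    ("soc_iui_cost", "38-40"): 6783,
    ("soc_iui_cost", "41-42"): 7142,
    ("soc_iui_cost", ">42"): 7385,
    ("soc_ivf_cost", "<35"): 18118,
    ("soc_ivf_cost", "35-37"): 21210,
    ("soc_ivf_cost", "38-40"): 25946,
    ("soc_ivf_cost", "41-42"): 33983,
    ("soc_ivf_cost", ">42"): 42060,
    ("soc_total_cost", "<35"): 24603,
    ("soc_total_cost", "35-37"): 27866,
    ("soc_total_cost", "38-40"): 32729,
    ("soc_total_cost", "41-42"): 41125,
    ("soc_total_cost", ">42"): 49445,
    ("cs_ti_ivf_cost", "<35"): 14708,
    ("cs_ti_ivf_cost", "35-37"): 15766,
    ("cs_ti_ivf_cost", "38-40"): 18129,
    ("cs_ti_ivf_cost", "41-42"): 20124,
    ("delta_ivf_cost", "<35"): -3410,
    ("delta_ivf_cost", "35-37"): -5444,
    ("delta_ivf_cost", "41-42"): -13859,
}
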
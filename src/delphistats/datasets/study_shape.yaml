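# Simulation config reproducing the design shape of the bundled
# two-round opioid-prescribing indicator panel: 24 panellists rating 20
# items in round 1 (15 tight low-score items, 5 broad mid-scale items),
# attrition 5/24 (expected round-2 panel of 19), and 13 derived items
# (one split pair + 11 modified rewordings).  These values are also the
# SimulationConfig defaults; the file exists as a template to edit.
n_panellists_round1: 24
n_items_round1: 20
n_modified_items: 13
attrition: 0.2083333333333333
feedback_shift: 0.3
seed: 0
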
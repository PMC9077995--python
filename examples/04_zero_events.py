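"""Upper bounds on a rare-event rate after observing zero events.

With x = 0 events in n patients and a Beta prior, the posterior upper
quantile bounds the event rate: observing nothing does not mean zero
risk. The table compares the uniform and Jeffreys priors with the
rule-of-three heuristic 3/n.
"""

from ecborrow.zero_numerator import JEFFREYS_PRIOR, UNIFORM_PRIOR, zero_event_table

table = zero_event_table([10, 30, 100, 300, 1000], [UNIFORM_PRIOR, JEFFREYS_PRIOR], 0.95)
table["3/n"] = 3.0 / table["n"]
print(table.to_string(index=False, float_format=lambda v: f"{v:.5f}"))
print(
    "\nEach entry is the 95th percentile of the Beta posterior for the event\n"
    "rate with zero observed events; the uniform-prior bound tracks 3/n for\n"
    "n >= 100, and a skeptical prior tightens it."
)
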
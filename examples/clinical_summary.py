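"""Response-rate estimation with an exact binomial confidence interval.

A single-arm trial observed 8 partial responses among 21 enrolled patients.
The summary reports the whole-number response rate and its Clopper-Pearson
95% CI, the standard exact interval for small trials.
"""

from pairedtumor import response_summary

rr = response_summary(8, 21)
print(f"response rate: {rr.successes}/{rr.total} = {rr.percent}%")
print(f"exact 95% CI: [{rr.lower:.3f}, {rr.upper:.3f}]")
# The interval is wide (n = 21): the data are consistent with true response
# rates anywhere between ~18% and ~62%.
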
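"""Seminatural-habitat profile over a potential-space x arable-cover gradient.

Each landscape's potential space is split between arable fields and
seminatural habitat; the table profiles the seminatural class.  Patch
sizes should peak where potential space is plentiful and little of it is
farmed.
"""

from agroscape import run_gradient_experiment

table = run_gradient_experiment(
    space_shares=[0.3, 0.6, 0.9],
    arable_shares=[0.3, 0.6, 0.9],
    sizes=[1.0],
    shapes=[1.5],
    seeds=[1, 2],
    nrow=80,
    ncol=80,
)

pivot = (
    table[table["metric"] == "area_mn"]
    .groupby(["space_share", "arable_share"])["value"]
    .mean()
    .unstack()
)
print("mean seminatural patch area (ha), space share (rows) x arable share (cols):")
print(pivot.round(2))
# largest patches in the bottom-left corner: much potential space, little farmed
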
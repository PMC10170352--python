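"""Extrapolate species abundances to unsequenced individuals.

A parataxonomic unit with 30 collected individuals at one site had 10
sequenced: 3 fell in one species and 7 in another.  The remaining 20
inherit those proportions (30% / 70%) by largest-remainder
apportionment, which conserves the total exactly.
"""

import pandas as pd

from aorweb.abundance_assign import PUCountTable, assign_counts, to_matrix

table = PUCountTable(
    counts=pd.DataFrame(
        [("PU012", "TEN01", 30), ("PU012", "TEN02", 7), ("PU013", "TEN01", 5)],
        columns=["pu", "site", "n"],
    ),
    sequenced=pd.DataFrame(
        [
            ("PU012", "TEN01", "PBS001", 3),
            ("PU012", "TEN01", "PBS002", 7),
            ("PU012", "TEN02", "PBS002", 2),
            ("PU013", "TEN01", "PBS003", 2),
        ],
        columns=["pu", "site", "pbs", "n"],
    ),
)

long = assign_counts(table)
print(long.to_string(index=False))
print()
print(to_matrix(long))
# At TEN01, PU012's 20 unsequenced individuals split 6 : 14 (30%/70%)
# on top of the 3 + 7 sequenced ones -> 9 and 21; column totals equal
# the collected counts at every site.
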
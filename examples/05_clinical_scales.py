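"""Score clinical stroke-rehabilitation instruments from item responses.

Berg Balance Scale (14 items, 0-4), Fugl-Meyer motor assessment (33 + 17
items, 0-2) and the Functional Independence Measure (13 motor + 5
cognitive items, 1-7) are totalled, and the FIM total is mapped to its
dependence category.
"""

import pandas as pd

from cerevess.scales import score_csv

row = {"subject": "demo-patient"}
row.update({f"berg_{i:02d}": 3 for i in range(1, 15)})
row.update({f"fma_upper_{i:02d}": 2 for i in range(1, 34)})
row.update({f"fma_lower_{i:02d}": 1 for i in range(1, 18)})
row.update({f"fim_motor_{i:02d}": 6 for i in range(1, 14)})
row.update({f"fim_cog_{i:02d}": 7 for i in range(1, 6)})

scored = score_csv(pd.DataFrame([row]))
print(scored.T.to_string(header=False))
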
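"""Small published datasets used as pipeline inputs.

The raw sequencing reads of the S15 HT-SELEX experiment are not publicly
deposited, but the per-round read totals are, and they are all that is
needed to reproduce the minimal cluster-enrichment thresholds.
"""

import pandas as pd

#: Per-round read totals (unfiltered / filtered) from the S15 HT-SELEX
#: sequencing experiment; rounds 4, 9, 10 and 11 were sequenced.
S15_ROUND_TOTALS = {
    "4": {"unfiltered": 10_978_044, "filtered": 4_150_081},
    "9": {"unfiltered": 10_854_647, "filtered": 407_138},
    "10": {"unfiltered": 5_764_497, "filtered": 481_763},
    "11": {"unfiltered": 5_269_551, "filtered": 545_142},
}


def s15_round_totals() -> pd.DataFrame:
    """Published S15 HT-SELEX read totals as a DataFrame indexed by round."""
    return pd.DataFrame(S15_ROUND_TOTALS).T.rename_axis("round")


def s15_filtered_totals() -> dict[str, int]:
    """Filtered (usable) read totals per round, for normalization."""
    return {r: v["filtered"] for r, v in S15_ROUND_TOTALS.items()}
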
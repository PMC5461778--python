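"""Aptamer template layout shared across the pipeline.

The selection library is built on an 87-nt template: a 15-nt 5' PCR primer,
a 30-nt randomized region, a 27-nt constant region and a 15-nt 3' PCR
primer.  All filtering, variable-region localization and background
simulation refer to these constants.
"""

PRIMER_5 = "TGCGTAACGTACACT"
PRIMER_3 = "ATGTCTCTAAGTACT"
CONSTANT_REGION = "TCATTCTATATACTTTGGAGTTTTAAA"
T7_PROMOTER = "TAATACGACTCACTATA"

VARIABLE_LENGTH = 30

#: Full expected insert: 5' primer + N30 + constant region + 3' primer.
TEMPLATE_LENGTH = (
    len(PRIMER_5) + VARIABLE_LENGTH + len(CONSTANT_REGION) + len(PRIMER_3)
)

#: Primer-delimited insert length bounds enforced by the read filter.
MIN_INSERT_LENGTH = 79
MAX_INSERT_LENGTH = 100


def expected_insert(variable_region: str) -> str:
    """Assemble a full-length insert from a variable region."""
    return PRIMER_5 + variable_region + CONSTANT_REGION + PRIMER_3
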
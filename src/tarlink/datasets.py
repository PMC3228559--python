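"""Published example data: mouse cortical E18/P7 read counts.

Exonic and intronic read counts for ten axon-guidance receptor/ligand genes
and three housekeeping genes at embryonic day 18 (E18) and postnatal day 7
(P7) mouse brain cortex, from a published developmental RNA-seq study, plus
the study's 2x2 table of intronic-vs-exonic expression-change directions
between the same stages. Used in the worked example and reproduction
checks; treated as input data, not values computed here.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "axon_guidance_counts",
    "housekeeping_counts",
    "e18_p7_change_counts",
]

# gene, E18 exonic, E18 intronic, P7 exonic, P7 intronic
_AXON_GUIDANCE = [
    ("Slit3", 43, 1012, 96, 827),
    ("Robo2", 2123, 4900, 1415, 796),
    ("Robo1", 1569, 1872, 425, 362),
    ("Nrp1", 991, 1688, 533, 416),
    ("Nrcam", 775, 1150, 1434, 730),
    ("Klf7", 1032, 826, 1088, 328),
    ("Gli3", 295, 133, 83, 51),
    ("Ephb2", 697, 845, 548, 456),
    ("Ephb1", 2006, 1773, 834, 435),
    ("Dcc", 1294, 6509, 281, 1246),
]

_HOUSEKEEPING = [
    ("Myc", 358, 13, 229, 8),
    ("Actb", 8847, 144, 8236, 503),
    ("Tuba1a", 4029, 63, 3724, 214),
]

# (exonic up & intronic up, exonic up & intronic down,
#  exonic down & intronic up, exonic down & intronic down)
E18_P7_CHANGE_TABLE = (43, 194, 9, 242)


def _to_long(rows: list[tuple]) -> pd.DataFrame:
    records = []
    for gene, e18_ex, e18_in, p7_ex, p7_in in rows:
        records.append(
            {"gene_id": gene, "stage": "E18", "exonic_reads": e18_ex, "intronic_reads": e18_in}
        )
        records.append(
            {"gene_id": gene, "stage": "P7", "exonic_reads": p7_ex, "intronic_reads": p7_in}
        )
    return pd.DataFrame(records)


def axon_guidance_counts() -> pd.DataFrame:
    """Long-format counts for the ten axon-guidance genes."""
    return _to_long(_AXON_GUIDANCE)


def housekeeping_counts() -> pd.DataFrame:
    """Long-format counts for Myc, Actb and Tuba1a."""
    return _to_long(_HOUSEKEEPING)


def e18_p7_change_counts() -> tuple[int, int, int, int]:
    """The published 2x2 direction-of-change cell counts (E18 -> P7)."""
    return E18_P7_CHANGE_TABLE
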
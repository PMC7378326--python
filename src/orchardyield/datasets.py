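"""Bundled benchmark tables from a published UAV apple-orchard survey.

Two small tables ship with the package so the statistics layer can be
exercised against published numbers without any imagery:

* :func:`canopy_counts` — visual fruit counts for 19 sample trees of one
  orchard row, split over the three canopy strata (top / middle /
  underside, the Nfcvt/Nfcvm/Nfcvun columns).
* :func:`detection_picture_counts` — detection outcomes (TP, FP, FN and the
  manually counted fruit number Nfp) for 20 evaluation pictures cropped
  from an orchard orthomosaic.

Only the raw count columns are stored; derived columns (totals, percentage
shares, precision/recall/F1/accuracy) are always recomputed by the package.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["canopy_counts", "detection_picture_counts"]

# (tree id, Nfcvt, Nfcvm, Nfcvun) — visual counts per canopy stratum
_CANOPY_COUNTS = (
    (1, 88, 95, 92),
    (5, 85, 101, 99),
    (9, 66, 77, 95),
    (14, 83, 68, 77),
    (17, 56, 75, 82),
    (24, 51, 93, 82),
    (25, 86, 87, 70),
    (27, 77, 107, 124),
    (32, 53, 78, 125),
    (33, 88, 117, 64),
    (34, 56, 89, 107),
    (43, 35, 202, 82),
    (48, 80, 117, 70),
    (50, 90, 95, 72),
    (51, 63, 44, 68),
    (56, 77, 84, 78),
    (57, 48, 128, 97),
    (59, 69, 88, 98),
    (62, 52, 110, 108),
)

# (picture id, TP, FP, FN, Nfp) — per-picture detection outcomes
_DETECTION_PICTURES = (
    (1, 70, 2, 8, 78),
    (2, 44, 3, 9, 53),
    (3, 62, 3, 6, 68),
    (4, 53, 4, 5, 58),
    (5, 20, 2, 4, 24),
    (6, 41, 3, 9, 50),
    (7, 67, 3, 5, 72),
    (8, 83, 5, 8, 91),
    (9, 86, 7, 10, 96),
    (10, 77, 6, 4, 81),
    (11, 80, 7, 6, 86),
    (12, 61, 3, 6, 67),
    (13, 75, 4, 1, 76),
    (14, 73, 5, 8, 81),
    (15, 30, 6, 4, 34),
    (16, 38, 5, 7, 45),
    (17, 56, 3, 8, 64),
    (18, 53, 7, 3, 56),
    (19, 67, 8, 9, 76),
    (20, 91, 2, 7, 98),
)


def canopy_counts() -> pd.DataFrame:
    """Per-tree visual stratum counts, indexed by tree id."""
    df = pd.DataFrame(_CANOPY_COUNTS,
                      columns=["Id", "Nfcvt", "Nfcvm", "Nfcvun"])
    return df.set_index("Id")


def detection_picture_counts() -> pd.DataFrame:
    """Per-picture TP/FP/FN/Nfp counts, indexed by picture id."""
    df = pd.DataFrame(_DETECTION_PICTURES,
                      columns=["Picture", "TP", "FP", "FN", "Nfp"])
    return df.set_index("Picture")
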
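"""Packaged reference fixtures.

``reference_item_table.csv`` transcribes the per-item screening statistics
of a published 50-item DSM-5 internet-addiction diagnostic instrument
(selected model, discrimination, S-X² fit, and two DIF Wald blocks per
item). It serves as a format reference for the screening reports this
package writes and as a frozen input for summary statistics.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

__all__ = ["load_reference_item_table", "REFERENCE_ITEM_TABLE_SHA256"]

REFERENCE_ITEM_TABLE_SHA256 = (
    "9b90d5dd49dbc750865803937a078f2e44759c25c64c36256adbc257052244c9"
)


def load_reference_item_table() -> pd.DataFrame:
    """Load the packaged 50-item reference screening table.

    Verifies the file checksum before parsing; a mismatch (a corrupted or
    edited fixture) raises instead of silently returning altered
    reference values.
    """
    ref = resources.files(__package__).joinpath("reference_item_table.csv")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != REFERENCE_ITEM_TABLE_SHA256:
        raise ValueError(
            f"reference item table checksum mismatch: {digest}"
        )
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw))
    if len(df) != 50:
        raise ValueError("reference item table must have 50 rows")
    return df
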
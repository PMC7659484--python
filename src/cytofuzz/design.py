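"""Cytokine dose design: the 16-condition key/dose table.

Conditions are coded by a 3-digit key over {0,1,2} giving the low / medium /
high level of IL-2, IL-7 and IL-15 respectively (e.g. ``200`` = high IL-2,
low IL-7, low IL-15), plus ``PC``, the no-cytokine control.  The digit→dose
mapping is fixed per cytokine:

==========  =====  ======  ======
digit       IL-2   IL-7    IL-15
==========  =====  ======  ======
0 (low)     1      6       6
1 (medium)  10     36      36
2 (high)    15     80      80
==========  =====  ======  ======

All doses are in ng/mL.
"""

from __future__ import annotations

import pandas as pd

#: digit -> dose (ng/mL) per cytokine
LEVELS = {
    "il2": {0: 1.0, 1: 10.0, 2: 15.0},
    "il7": {0: 6.0, 1: 36.0, 2: 80.0},
    "il15": {0: 6.0, 1: 36.0, 2: 80.0},
}

#: the 15 coded conditions in table order, preceded by the control
CONDITION_KEYS = (
    "PC",
    "000", "100", "200",
    "010", "020", "001", "002",
    "110", "101", "011",
    "220", "202", "022",
    "111", "222",
)

DESIGN_COLUMNS = ("key", "il2_ng_ml", "il7_ng_ml", "il15_ng_ml")


def doses_for_key(key: str) -> tuple[float, float, float]:
    """Doses (IL-2, IL-7, IL-15) in ng/mL for a condition key."""
    if key == "PC":
        return (0.0, 0.0, 0.0)
    if len(key) != 3 or any(ch not in "012" for ch in key):
        raise ValueError(f"malformed condition key: {key!r}")
    d2, d7, d15 = (int(ch) for ch in key)
    return (LEVELS["il2"][d2], LEVELS["il7"][d7], LEVELS["il15"][d15])


def make_design_table() -> pd.DataFrame:
    """The full 16-row design table (control plus 15 coded conditions)."""
    rows = []
    for key in CONDITION_KEYS:
        il2, il7, il15 = doses_for_key(key)
        rows.append((key, il2, il7, il15))
    return pd.DataFrame(rows, columns=list(DESIGN_COLUMNS))


def validate_design(design: pd.DataFrame) -> None:
    """Check design-table invariants; raise ``ValueError`` on violation."""
    missing = set(DESIGN_COLUMNS) - set(design.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    if design["key"].duplicated().any():
        dups = design.loc[design["key"].duplicated(), "key"].tolist()
        raise ValueError(f"duplicate condition keys: {dups}")
    doses = design[["il2_ng_ml", "il7_ng_ml", "il15_ng_ml"]].to_numpy()
    if (doses < 0).any():
        raise ValueError("negative dose in design table")
    if "PC" in set(design["key"]):
        pc = design.loc[design["key"] == "PC"].iloc[0]
        if tuple(pc[["il2_ng_ml", "il7_ng_ml", "il15_ng_ml"]]) != (0.0, 0.0, 0.0):
            raise ValueError("PC control must map to (0, 0, 0) ng/mL")


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_design(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype={"key": str})
    validate_design(design)
    return design
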
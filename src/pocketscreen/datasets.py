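"""Bundled reference tables.

``load_serm_reference`` returns the published summary of SERM effects on
microtubules: per-compound PocketFeature Score, normalized polymerization
end point (MEP, % of the paclitaxel reference) and Vmax (%/min) with their
fold changes over the DMSO vehicle, abnormalities per cell, SiR-tubulin
displacement call, and live-imaging potencies (EC50 in µM for
proliferation inhibition and for cell death at 24/48 h). Missing entries
(not assigned / not applicable) are NaN.

Note the printed fold changes were computed from unrounded raw statistics,
so a few rows (e.g. the paclitaxel and lasofoxifene MEP fold changes)
differ in the last digit from the ratio of the rounded columns.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_serm_reference", "NOCODAZOLE_CELL_COUNTS"]

#: Cells scored per condition in the nocodazole-challenge experiment.
NOCODAZOLE_CELL_COUNTS = {"DMSO": 627, "TAX": 139, "RAL": 520, "LAS": 138}


def load_serm_reference() -> pd.DataFrame:
    """The SERM microtubule-modulation summary table, indexed by ligand."""
    ref = resources.files("pocketscreen.data").joinpath("serm_microtubule_table.csv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path)
    return df.set_index("ligand")
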
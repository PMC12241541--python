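"""Default whole-brain parcellation labels.

The default scheme mirrors a combined atlas of 400 cortical regions,
28 cerebellar regions and 54 subcortical regions (482 total).  Labels are
synthetic placeholders; only counts and group structure matter downstream.
"""

from __future__ import annotations

import pandas as pd

CORTICAL_NETWORKS = (
    "Vis",
    "SomMot",
    "DorsAttn",
    "SalVentAttn",
    "Limbic",
    "Cont",
    "Default",
)

DEFAULT_N_CORTICAL = 400
DEFAULT_N_CEREBELLAR = 28
DEFAULT_N_SUBCORTICAL = 54


def default_parcellation(
    n_cortical: int = DEFAULT_N_CORTICAL,
    n_cerebellar: int = DEFAULT_N_CEREBELLAR,
    n_subcortical: int = DEFAULT_N_SUBCORTICAL,
) -> pd.DataFrame:
    """Return a region table with ``label``, ``group`` and ``structure`` columns.

    ``structure`` is one of ``cortex``/``cerebellum``/``subcortex``; ``group``
    subdivides cortical regions into seven canonical resting-state networks.
    """
    rows = []
    for i in range(n_cortical):
        hemi = "LH" if i < n_cortical // 2 else "RH"
        net = CORTICAL_NETWORKS[i % len(CORTICAL_NETWORKS)]
        rows.append((f"{hemi}_{net}_{i + 1:03d}", net, "cortex"))
    for i in range(n_cerebellar):
        rows.append((f"Cerebellum_{i + 1:02d}", "Cerebellum", "cerebellum"))
    for i in range(n_subcortical):
        rows.append((f"Subcortex_{i + 1:02d}", "Subcortex", "subcortex"))
    return pd.DataFrame(rows, columns=["label", "group", "structure"])
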
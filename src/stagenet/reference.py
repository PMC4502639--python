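"""Published reference values for the OSCC stage-signature analysis design.

``REFERENCE_KEY_HUBS`` is the published 13-gene key-hub signature of
early-vs-late oral squamous cell carcinoma stage, with each gene's scaled
intramodular connectivity (K), gene significance (GS) and bootstrap
elastic-net inclusion frequency (f, out of 1000 bootstraps).  The selection
thresholds in force were GS > 0.2, K > 0.3 and f > 675; the signature's
boundary case sits at f = 676.

``REFERENCE_COHORTS`` lists the public GEO cohorts that such a merged
compendium draws on, with tumor/normal sample counts after array-level
quality control (355 tumors and 131 normals in total).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["REFERENCE_KEY_HUBS", "REFERENCE_COHORTS", "reference_key_hub_table",
           "reference_cohort_table"]

# gene symbol -> (scaled connectivity K, gene significance GS, frequency f)
REFERENCE_KEY_HUBS: dict[str, tuple[float, float, int]] = {
    "CBX3": (0.82, 0.43, 982),
    "PSPH": (0.37, 0.32, 980),
    "ATP2C1": (0.91, 0.40, 948),
    "SNX10": (0.72, 0.38, 936),
    "MMD": (0.57, 0.37, 936),
    "ATP13A3": (0.74, 0.38, 929),
    "GLS": (0.70, 0.37, 923),
    "EGFR": (0.63, 0.33, 869),
    "GNA12": (0.80, 0.37, 840),
    "ABCC4": (0.46, 0.32, 770),
    "HMGB3": (0.74, 0.36, 765),
    "HMGA2": (0.81, 0.34, 744),
    "HOXA1": (0.75, 0.34, 676),
}

# GEO accession -> (tumor, normal) counts after initial preprocessing / QC.
REFERENCE_COHORTS: dict[str, tuple[int, int]] = {
    "GSE31056": (23, 24),
    "GSE9844": (26, 12),
    "GSE30784": (165, 45),
    "GSE3524": (16, 4),
    "GSE42743": (73, 27),
    "GSE2280": (22, 5),
    "GSE6791": (30, 14),
}


def reference_key_hub_table() -> pd.DataFrame:
    """The published signature as a DataFrame with columns K, GS, f."""
    return pd.DataFrame(
        [(g, k, gs, f) for g, (k, gs, f) in REFERENCE_KEY_HUBS.items()],
        columns=["gene", "K", "GS", "f"],
    ).set_index("gene")


def reference_cohort_table() -> pd.DataFrame:
    """Cohort sample bookkeeping as a DataFrame with tumor/normal counts."""
    return pd.DataFrame(
        [(a, t, n) for a, (t, n) in REFERENCE_COHORTS.items()],
        columns=["accession", "tumor", "normal"],
    ).set_index("accession")
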